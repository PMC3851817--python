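"""Synthetic datasets with the statistical structure the analyses assume.

The default preset mirrors a coastal-plain phylogeography study design:
~22 georeferenced populations of ~10 mtDNA sequences each (1140 bp,
7.12e-9 substitutions/site/year, 3 generations/year), four spatially
contiguous genetic groups, star-like expansion genealogies, and allozyme
expected heterozygosity declining with latitude away from a southern
refugium.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .coalescent import (
    GENERATION_TIME_YEARS,
    PopulationTreeModel,
    build_hypothesis_model,
    mutate_on_tree,
    simulate_gene_tree,
    single_population_model,
)
from .haplotypes import (
    HaplotypeAlignment,
    InputError,
    SequenceRecord,
    SiteInfo,
)
from .mismatch import simulate_pairwise_differences


@dataclass
class SyntheticSpec:
    seed: int = 0
    n_populations: int = 22
    samples_per_pop: int = 10
    L: int = 1140
    mu_site_year: float = 7.12e-9
    generation_time: float = GENERATION_TIME_YEARS
    demography: str = "structured"  # constant | sudden_expansion | structured
    n_groups: int = 4
    overall_ne: float = 6.05e5
    tau: float = 2.4
    theta0: float = 0.5
    theta1: float = 500.0
    group_divergence_gen: float | None = None
    barrier_after_group: int | None = None

    def __post_init__(self):
        if min(self.n_populations, self.samples_per_pop, self.L) < 1:
            raise InputError("counts must be >= 1")


def _coordinates(
    n_populations: int, n_groups: int, rng: np.random.Generator
) -> tuple[dict[str, SiteInfo], dict[str, str]]:
    """Cluster centers along a latitude gradient with jitter; groups are
    latitudinally contiguous (southern group = putative refugium)."""
    pops = {}
    group_of = {}
    per_group = int(math.ceil(n_populations / n_groups))
    i = 0
    for g in range(n_groups):
        center_lat = 26.0 + 2.0 * g
        center_lon = -84.0 + 1.2 * g
        for _ in range(per_group):
            if i >= n_populations:
                break
            name = f"P{i + 1:02d}"
            pops[name] = SiteInfo(
                latitude=float(center_lat + rng.normal(scale=0.35)),
                longitude=float(center_lon + rng.normal(scale=0.35)),
                n=0,
            )
            group_of[name] = f"G{g + 1}"
            i += 1
    return pops, group_of


def make_sequence_dataset(spec: SyntheticSpec):
    """Simulate an aligned sequence dataset plus site coordinates.

    Returns ``(alignment, group_of)``: the alignment carries population
    labels and georeferenced site metadata; ``group_of`` maps populations to
    their generating group (the planted truth for recovery tests).
    """
    rng = np.random.default_rng(spec.seed)
    mu_locus_gen = spec.mu_site_year * spec.L * spec.generation_time

    sites, group_of = _coordinates(spec.n_populations, spec.n_groups, rng)
    pop_names = sorted(sites)

    if spec.demography == "constant":
        model = single_population_model(
            spec.overall_ne, sample_size=spec.n_populations * spec.samples_per_pop
        )
        tree = simulate_gene_tree(model, seed=int(rng.integers(2**31 - 1)))
        aln = mutate_on_tree(
            tree, mu_locus_gen, spec.L, seed=int(rng.integers(2**31 - 1))
        )
        records = _relabel_to_pops(aln, pop_names, spec.samples_per_pop)
    elif spec.demography == "sudden_expansion":
        aln = make_expansion_dataset(
            spec.tau, spec.theta0, spec.theta1,
            n=spec.n_populations * spec.samples_per_pop, L=spec.L,
            seed=int(rng.integers(2**31 - 1)),
        )
        records = _relabel_to_pops(aln, pop_names, spec.samples_per_pop)
    elif spec.demography == "structured":
        div = spec.group_divergence_gen
        if div is None:
            # deepest intraspecific split scale: 0.377 Ma at 3 gen/yr
            div = 1.13e6
        groups = sorted(set(group_of.values()))
        pops_per_group = [
            sum(1 for p in pop_names if group_of[p] == g) for g in groups
        ]
        model = _structured_model(
            spec.overall_ne, spec.n_groups, div,
            samples=[spec.samples_per_pop * k for k in pops_per_group],
        )
        tree = simulate_gene_tree(model, seed=int(rng.integers(2**31 - 1)))
        aln = mutate_on_tree(
            tree, mu_locus_gen, spec.L, seed=int(rng.integers(2**31 - 1))
        )
        records = _relabel_structured(aln, pop_names, group_of, spec.samples_per_pop)
    else:
        raise InputError(f"unknown demography {spec.demography!r}")

    for name in pop_names:
        sites[name] = SiteInfo(
            latitude=sites[name].latitude, longitude=sites[name].longitude,
            n=sum(1 for r in records if r.population == name),
        )
    out = HaplotypeAlignment(records=records, populations=sites)
    return out, group_of


def _structured_model(
    overall_ne, n_groups, divergence_gen, samples,
    expansion_gen: float = 1.5e5, refugial_fraction: float = 0.02,
):
    """Star divergence of n_groups lineages at ``divergence_gen``, each
    group expanding from a small refugial size at ``expansion_gen`` (a
    Late-Pleistocene-scale expansion producing star-like within-group
    genealogies)."""
    if isinstance(samples, int):
        samples = [samples] * n_groups
    model = build_hypothesis_model(
        "four_refugia",
        overall_ne=overall_ne,
        t_total=divergence_gen,
        n_tips=n_groups,
        sample_sizes=list(samples),
    )
    for tip in model.tips:
        br = model.branches[tip]
        recent_ne = overall_ne
        old_ne = max(refugial_fraction * overall_ne / n_groups, 1.0)
        br.ne_segments = [
            (0.0, expansion_gen, recent_ne),
            (expansion_gen, br.t_top, old_ne),
        ]
    model.label = f"structured_{n_groups}"
    return model


def _relabel_to_pops(aln, pop_names, samples_per_pop):
    records = []
    k = 0
    for r in aln.records:
        pop = pop_names[min(k // samples_per_pop, len(pop_names) - 1)]
        records.append(
            SequenceRecord(id=f"{pop}|s{k % samples_per_pop + 1}",
                           sequence=r.sequence, population=pop)
        )
        k += 1
    return records


def _relabel_structured(aln, pop_names, group_of, samples_per_pop):
    """Assign each simulated group's samples to that group's populations."""
    groups = sorted({g for g in group_of.values()})
    pops_by_group = {
        g: [p for p in pop_names if group_of[p] == g] for g in groups
    }
    counters = {g: 0 for g in groups}
    records = []
    for r in aln.records:
        tip = r.population  # pop1..popK from the simulator
        g = groups[int(tip.replace("pop", "")) - 1]
        pops = pops_by_group[g]
        k = counters[g]
        pop = pops[min(k // samples_per_pop, len(pops) - 1)]
        counters[g] += 1
        records.append(
            SequenceRecord(id=f"{pop}|s{k + 1}", sequence=r.sequence,
                           population=pop)
        )
    return records


def make_expansion_dataset(
    tau: float, theta0: float, theta1: float, n: int, L: int,
    seed: int | None = None,
) -> HaplotypeAlignment:
    """Infinite-sites alignment simulated under the sudden-expansion
    coalescent (mutational time; instantaneous size change at tau)."""
    if tau < 0 or theta0 < 0 or theta1 < 0:
        raise InputError("tau and thetas must be nonnegative")
    rng = np.random.default_rng(seed)
    # reuse the pairwise simulator's branch bookkeeping by regenerating
    # the branch list here (mask, length) and writing actual sequences
    masks, lengths = _expansion_branches(n, tau, theta0, theta1, rng)
    free = list(rng.permutation(L))
    seqs = [["A"] * L for _ in range(n)]
    for mask, length in zip(masks, lengths):
        nm = rng.poisson(length / 2.0)
        for _ in range(nm):
            if not free:
                raise OverflowError(
                    "infinite-sites overflow: more mutations than sites"
                )
            pos = free.pop()
            alt = "CGT"[rng.integers(3)]
            for i in range(n):
                if mask >> i & 1:
                    seqs[i][pos] = alt
    records = [
        SequenceRecord(id=f"P01|s{i + 1}", sequence="".join(s), population="P01")
        for i, s in enumerate(seqs)
    ]
    return HaplotypeAlignment(records=records)


def _expansion_branches(n, tau, theta0, theta1, rng):
    masks = [1 << i for i in range(n)]
    opens = [0.0] * n
    out_masks, out_lens = [], []
    t = 0.0
    k = n
    floor = 1e-8
    while k > 1:
        theta = theta1 if t < tau else theta0
        rate = (k * (k - 1) / 2.0) / max(theta, floor)
        w = 0.0 if theta <= floor else rng.exponential(1.0 / rate)
        if t < tau and t + w > tau:
            dt = tau - t
            opens = [o + dt for o in opens]
            t = tau
            continue
        opens = [o + w for o in opens]
        t += w
        i, j = sorted(rng.choice(k, size=2, replace=False))
        out_masks += [masks[i], masks[j]]
        out_lens += [opens[i], opens[j]]
        merged = masks[i] | masks[j]
        masks = [m for idx, m in enumerate(masks) if idx not in (i, j)] + [merged]
        opens = [o for idx, o in enumerate(opens) if idx not in (i, j)] + [0.0]
        k -= 1
    return out_masks, out_lens


def make_allozyme_dataset(
    populations: dict[str, SiteInfo] | int = 34,
    loci: int = 11,
    cline_slope: float = -0.008,
    he_at_25N: float = 0.15,
    refuge_lat_cutoff: float = 28.0,
    private_allele_freq: float = 0.08,
    concentration: float = 50.0,
    sample_size: int = 24,
    seed: int | None = None,
):
    """Allozyme frequencies with a planted latitudinal He cline and extra
    private alleles below the refugium latitude cutoff.

    Per population and locus the major-allele frequency is drawn from a
    Dirichlet (Beta) centred so that the expected heterozygosity follows
    He(lat) = he_at_25N + cline_slope * (lat - 25), with concentration
    ``concentration`` controlling sampling noise.  Returns
    ``(AllozymeDataset, refuge_flags)``.
    """
    from .allozymes import AllozymeDataset

    rng = np.random.default_rng(seed)
    if isinstance(populations, int):
        pops = {}
        for i in range(populations):
            lat = 25.0 + 8.0 * i / max(populations - 1, 1)
            pops[f"a{i + 1:02d}"] = SiteInfo(
                latitude=float(lat + rng.normal(scale=0.2)),
                longitude=float(-82.0 + rng.normal(scale=0.5)),
                n=sample_size,
            )
    else:
        pops = populations

    locus_names = [f"L{i + 1:02d}" for i in range(loci)]
    freqs = {}
    refuge = {}
    for pop, info in pops.items():
        refuge[pop] = info.latitude < refuge_lat_cutoff
        for locus in locus_names:
            he_target = he_at_25N + cline_slope * (info.latitude - 25.0)
            he_target = min(max(he_target, 0.005), 0.5)
            # two-allele locus: He = 2p(1-p) -> minor allele target p*
            p_star = (1.0 - math.sqrt(1.0 - 2.0 * he_target)) / 2.0
            p = rng.beta(concentration * p_star, concentration * (1 - p_star))
            d = {"01": 1.0 - p, "02": p}
            if refuge[pop] and private_allele_freq > 0 and rng.random() < 0.5:
                eps = private_allele_freq
                d = {a: f * (1 - eps) for a, f in d.items()}
                d[f"prv"] = eps
            # renormalize exactly
            s = sum(d.values())
            d = {a: f / s for a, f in d.items()}
            freqs[(pop, locus)] = d
    ds = AllozymeDataset(populations=pops, loci=locus_names, freqs=freqs)
    return ds, refuge
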