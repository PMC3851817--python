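"""Polymorphism summaries and neutrality tests.

Implements Watterson/Nei diversity summaries, Fu's Fs (exact, via unsigned
Stirling numbers of the first kind and the Ewens sampling formula),
Ramos-Onsins & Rozas' R2, Fay & Wu's H with outgroup polarization, the
McDonald-Kreitman test (Nei-Gojobori site classification, vertebrate
mitochondrial code), and fixed-S coalescent simulation p-values.

p-value convention throughout: add-one correction, (1 + count) / (reps + 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations as _perms

import numpy as np
from scipy import stats as _st
from Bio.Data import CodonTable

from .haplotypes import (
    MISSING,
    HaplotypeAlignment,
    InputError,
    collapse_haplotypes,
    n_differences,
)


class SampleSizeError(ValueError):
    pass


class UndefinedStatisticError(ValueError):
    pass


def harmonic_number(m: int) -> float:
    """a_n style harmonic sum: sum_{i=1}^{m} 1/i."""
    return sum(1.0 / i for i in range(1, m + 1))


@dataclass
class DiversitySummary:
    n: int
    S: int
    h: int
    Hd: float
    pi: float
    k: float
    thetaW_site: float
    thetaW_locus: float
    a_n: float
    L: int

    def to_dict(self):
        return {
            "n": self.n, "S": self.S, "h": self.h, "Hd": self.Hd,
            "pi": self.pi, "k": self.k, "thetaW_site": self.thetaW_site,
            "thetaW_locus": self.thetaW_locus, "a_n": self.a_n, "L": self.L,
        }


@dataclass
class NeutralityResult:
    statistic: str
    value: float
    p_values: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)


def segregating_sites(aln: HaplotypeAlignment) -> int:
    """Sites with two or more distinct non-missing states."""
    M = aln.matrix()
    present = np.zeros(M.shape[1], dtype=int)
    S = np.zeros(M.shape[1], dtype=int)
    for b in b"ACGT":
        hit = (M == bytes([b])).any(axis=0)
        S += hit
    return int(np.sum(S >= 2))


def mean_pairwise_differences(aln: HaplotypeAlignment) -> float:
    from .haplotypes import pairwise_difference_matrix

    n = aln.n
    D = pairwise_difference_matrix(aln)
    return float(D.sum() / 2.0 / (n * (n - 1) / 2))


def watterson_theta(n: int, S: int, L: int) -> tuple[float, float, float]:
    """(theta_per_site, theta_per_locus, a_n) from sample counts alone."""
    if n < 2:
        raise SampleSizeError("need at least 2 sequences")
    a_n = harmonic_number(n - 1)
    theta_locus = S / a_n
    return theta_locus / L, theta_locus, a_n


def haplotype_diversity(counts: list[int]) -> float:
    """Nei's Hd = n/(n-1) * (1 - sum p_i^2)."""
    n = sum(counts)
    if n < 2:
        raise SampleSizeError("need at least 2 sequences")
    freqs_sq = sum((c / n) ** 2 for c in counts)
    return n / (n - 1) * (1 - freqs_sq)


def diversity_summary(aln: HaplotypeAlignment) -> DiversitySummary:
    if aln.n < 2:
        raise SampleSizeError("need at least 2 sequences")
    if not aln.haplotypes:
        aln = collapse_haplotypes(aln)
    S = segregating_sites(aln)
    k = mean_pairwise_differences(aln)
    L = aln.site_count
    th_site, th_locus, a_n = watterson_theta(aln.n, S, L)
    counts = [c for _, c, _ in aln.haplotypes]
    return DiversitySummary(
        n=aln.n, S=S, h=len(aln.haplotypes), Hd=haplotype_diversity(counts),
        pi=k / L, k=k, thetaW_site=th_site, thetaW_locus=th_locus,
        a_n=a_n, L=L,
    )


# ---------------------------------------------------------------------------
# Fu's Fs

@lru_cache(maxsize=8)
def _stirling_row(n: int) -> tuple[int, ...]:
    """Unsigned Stirling numbers of the first kind |s(n, k)| for k=0..n.

    Exact integer recursion |s(n+1,k)| = |s(n,k-1)| + n*|s(n,k)|; Python
    bigints keep this exact at any n we use (log-magnitudes are taken with
    math.log, which accepts arbitrary-precision ints).
    """
    row = [1]  # n = 0
    for m in range(n):
        new = [0] * (m + 2)
        for k in range(m + 1):
            new[k + 1] += row[k]
            new[k] += m * row[k]
        row = new
    return tuple(row)


def fu_fs(k_obs: int, n: int, theta: float) -> float:
    """Fu's Fs from the Ewens sampling formula.

    S' = P(K >= k_obs | theta) = sum_{k>=k_obs} |s(n,k)| theta^k / theta_(n),
    Fs = ln(S' / (1 - S')).  theta is the mean number of pairwise differences.
    Returns +inf when k_obs = 1 (S' = 1).
    """
    if theta <= 0:
        raise UndefinedStatisticError("theta must be positive")
    if not 1 <= k_obs <= n:
        raise InputError("k_obs must be in [1, n]")
    if k_obs == 1:
        return math.inf
    row = _stirling_row(n)
    log_theta = math.log(theta)
    log_rising = sum(math.log(theta + i) for i in range(n))
    log_terms = [
        math.log(row[k]) + k * log_theta - log_rising for k in range(1, n + 1)
    ]
    mx = max(log_terms)
    probs = np.exp(np.array(log_terms) - mx)
    probs /= probs.sum()  # exact normalization of the Ewens K-distribution
    s_prime = float(probs[k_obs - 1:].sum())
    if s_prime >= 1.0:
        return math.inf
    if s_prime <= 0.0:
        return -math.inf
    return math.log(s_prime / (1.0 - s_prime))


def fu_fs_from_alignment(aln: HaplotypeAlignment) -> float:
    if not aln.haplotypes:
        aln = collapse_haplotypes(aln)
    return fu_fs(len(aln.haplotypes), aln.n, mean_pairwise_differences(aln))


# ---------------------------------------------------------------------------
# R2

def singleton_counts(aln: HaplotypeAlignment) -> list[int]:
    """U_i: number of segregating sites where sequence i carries the unique
    minor state (minor-state count 1 among non-missing calls)."""
    seqs = aln.sequences()
    n = len(seqs)
    U = [0] * n
    for site in range(aln.site_count):
        col = [s[site] for s in seqs]
        present = [(i, c) for i, c in enumerate(col) if c not in MISSING]
        states = {}
        for i, c in present:
            states.setdefault(c, []).append(i)
        if len(states) < 2:
            continue
        for c, idxs in states.items():
            if len(idxs) == 1 and len(present) > 2:
                U[idxs[0]] += 1
        if len(present) == 2 and len(states) == 2:
            # a two-call column: both carriers are singletons
            for c, idxs in states.items():
                U[idxs[0]] += 1
    return U


def r2_statistic(aln: HaplotypeAlignment) -> float:
    """Ramos-Onsins & Rozas R2 = sqrt(mean (U_i - k/2)^2) / S."""
    S = segregating_sites(aln)
    if S == 0:
        raise UndefinedStatisticError("no segregating sites")
    k = mean_pairwise_differences(aln)
    U = singleton_counts(aln)
    return _r2_from_parts(U, k, S)


def _r2_from_parts(U, k: float, S: int) -> float:
    n = len(U)
    msq = sum((u - k / 2.0) ** 2 for u in U) / n
    return math.sqrt(msq) / S


# ---------------------------------------------------------------------------
# Fay & Wu's H

@dataclass
class FayWuResult:
    H: float
    theta_pi: float
    theta_H: float
    S_polarized: int
    S_dropped: int


def fay_wu_h(aln: HaplotypeAlignment, outgroup: str) -> FayWuResult:
    """Fay & Wu's H = theta_pi - theta_H with outgroup polarization.

    At each segregating site the derived state is the ingroup allele differing
    from the outgroup; sites where the outgroup matches neither ingroup allele
    (or is missing) are dropped and counted.
    """
    outgroup = outgroup.upper()
    if len(outgroup) != aln.site_count:
        raise InputError("outgroup length does not match alignment")
    seqs = aln.sequences()
    n = len(seqs)
    freqs: dict[int, int] = {}
    dropped = 0
    for site in range(aln.site_count):
        col = [s[site] for s in seqs]
        present = [c for c in col if c not in MISSING]
        states = sorted(set(present))
        if len(states) < 2:
            continue
        anc = outgroup[site]
        if anc in MISSING or anc not in states:
            dropped += 1
            continue
        derived = [c for c in present if c != anc]
        i = len(derived)
        if 0 < i < len(present):
            # pool all non-ancestral states as derived (multi-allelic rare)
            freqs[i] = freqs.get(i, 0) + 1
    theta_pi = sum(2.0 * cnt * i * (n - i) for i, cnt in freqs.items()) / (n * (n - 1))
    theta_H = sum(2.0 * cnt * i * i for i, cnt in freqs.items()) / (n * (n - 1))
    S_pol = sum(freqs.values())
    if S_pol == 0 and dropped > 0 and segregating_sites(aln) > 0:
        raise UndefinedStatisticError("no polarizable segregating sites")
    return FayWuResult(
        H=theta_pi - theta_H, theta_pi=theta_pi, theta_H=theta_H,
        S_polarized=S_pol, S_dropped=dropped,
    )


# ---------------------------------------------------------------------------
# McDonald-Kreitman

_MITO_TABLE = CodonTable.unambiguous_dna_by_id[2]  # vertebrate mitochondrial


def _translate(codon: str) -> str | None:
    if any(c in MISSING for c in codon):
        return None
    if codon in _MITO_TABLE.stop_codons:
        return "*"
    return _MITO_TABLE.forward_table.get(codon)


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """Mean (synonymous, nonsynonymous) changes over minimal mutational
    pathways between two codons (Nei-Gojobori single-pathway logic)."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    syn_tot = nsyn_tot = 0.0
    npaths = 0
    for order in _perms(diff):
        cur = list(c1)
        syn = nsyn = 0
        ok = True
        for pos in order:
            prev = "".join(cur)
            cur[pos] = c2[pos]
            nxt = "".join(cur)
            aa1, aa2 = _translate(prev), _translate(nxt)
            if aa1 is None or aa2 is None:
                ok = False
                break
            if aa1 == aa2:
                syn += 1
            else:
                nsyn += 1
        if ok:
            syn_tot += syn
            nsyn_tot += nsyn
            npaths += 1
    if npaths == 0:
        return 0.0, float(len(diff))
    return syn_tot / npaths, nsyn_tot / npaths


@dataclass
class MKResult:
    table: list[list[float]]  # rows syn/nonsyn, cols polymorphic/fixed
    p: float | None
    applicable: bool


def mcdonald_kreitman(
    ingroup: HaplotypeAlignment, outgroup: str, frame_offset: int = 0
) -> MKResult:
    """MK 2x2 test on a coding alignment against a single outgroup sequence.

    Codon-by-codon classification of variable positions as synonymous or
    nonsynonymous (averaging over minimal mutational pathways in multi-hit
    codons) and polymorphic (variable within the ingroup) or fixed (ingroup
    monomorphic, differing from the outgroup).  Two-sided Fisher exact p.
    """
    outgroup = outgroup.upper()
    seqs = [s for s in ingroup.sequences()]
    L = ingroup.site_count
    syn_poly = nsyn_poly = syn_fix = nsyn_fix = 0.0
    for start in range(frame_offset, L - 2, 3):
        in_codons = []
        for s in seqs:
            cod = s[start:start + 3]
            if all(c not in MISSING for c in cod):
                in_codons.append(cod)
        out_cod = outgroup[start:start + 3]
        if not in_codons or any(c in MISSING for c in out_cod):
            continue
        uniq = sorted(set(in_codons))
        if len(uniq) > 1:
            # polymorphic codon: classify against the most common variant
            ref = max(uniq, key=in_codons.count)
            for alt in uniq:
                if alt == ref:
                    continue
                s_c, n_c = _pathway_counts(ref, alt)
                syn_poly += s_c
                nsyn_poly += n_c
        elif uniq[0] != out_cod:
            s_c, n_c = _pathway_counts(uniq[0], out_cod)
            syn_fix += s_c
            nsyn_fix += n_c
    table = [[syn_poly, syn_fix], [nsyn_poly, nsyn_fix]]
    margins = (
        syn_poly + syn_fix, nsyn_poly + nsyn_fix,
        syn_poly + nsyn_poly, syn_fix + nsyn_fix,
    )
    if any(m == 0 for m in margins):
        return MKResult(table=table, p=None, applicable=False)
    rounded = [[round(v) for v in row] for row in table]
    _, p = _st.fisher_exact(rounded, alternative="two-sided")
    return MKResult(table=table, p=float(p), applicable=True)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p by hypergeometric enumeration (scipy)."""
    _, p = _st.fisher_exact(table, alternative="two-sided")
    return float(p)


# ---------------------------------------------------------------------------
# Fixed-S coalescent null simulations

def _simulate_fixed_s(n: int, S: int, rng: np.random.Generator):
    """One constant-size coalescent genealogy with S mutations placed
    uniformly on the total branch length.  Returns the list of descendant-set
    bitmasks, one per mutation (derived carriers)."""
    # active lineages as bitmasks over samples, with accumulated branch length
    masks = [1 << i for i in range(n)]
    opens = [0.0] * n
    branches: list[tuple[int, float]] = []  # closed (mask, length)
    k = n
    while k > 1:
        t = rng.exponential(1.0 / (k * (k - 1) / 2.0))
        opens = [o + t for o in opens]
        i, j = sorted(rng.choice(k, size=2, replace=False))
        branches.append((masks[i], opens[i]))
        branches.append((masks[j], opens[j]))
        merged = masks[i] | masks[j]
        masks = [m for idx, m in enumerate(masks) if idx not in (i, j)] + [merged]
        opens = [o for idx, o in enumerate(opens) if idx not in (i, j)] + [0.0]
        k -= 1
    lens = np.array([b[1] for b in branches])
    probs = lens / lens.sum()
    picks = rng.choice(len(branches), size=S, p=probs)
    return [branches[i][0] for i in picks]


def _stats_from_masks(masks, n: int):
    """(k, K_haplotypes, U, freqs) from infinite-sites mutation masks."""
    full = (1 << n) - 1
    derived_counts = [bin(m).count("1") for m in masks]
    k = sum(2.0 * i * (n - i) for i in derived_counts) / (n * (n - 1))
    # haplotypes: per-sample tuple of carried mutations
    carried = [[] for _ in range(n)]
    for mi, m in enumerate(masks):
        mm = m
        while mm:
            low = mm & -mm
            carried[low.bit_length() - 1].append(mi)
            mm ^= low
    K = len({tuple(c) for c in carried})
    U = [0] * n
    for m, dc in zip(masks, derived_counts):
        if dc == 1:
            U[m.bit_length() - 1] += 1
        elif dc == n - 1:
            inv = full ^ m
            U[inv.bit_length() - 1] += 1
    freqs = derived_counts
    return k, K, U, freqs


def simulation_pvalue(
    stat: str, observed: float, n: int, S: int,
    reps: int = 10000, seed: int | None = None,
) -> dict:
    """Null distribution of Fs, R2 or H under the fixed-S constant-size
    coalescent (Hudson's scheme: S mutations placed uniformly on the tree).

    Lower-tail p (expansion/sweep direction) is the headline; the upper tail
    is reported alongside.  Add-one corrected.
    """
    if reps < 100:
        raise InputError("reps must be >= 100")
    if stat not in ("Fs", "R2", "H"):
        raise InputError(f"unknown statistic {stat!r}")
    rng = np.random.default_rng(seed)
    sims = np.empty(reps)
    for r in range(reps):
        masks = _simulate_fixed_s(n, S, rng)
        k, K, U, freqs = _stats_from_masks(masks, n)
        if stat == "Fs":
            sims[r] = fu_fs(K, n, k) if k > 0 else math.inf
        elif stat == "R2":
            sims[r] = _r2_from_parts(U, k, S)
        else:
            th_pi = k
            th_H = sum(2.0 * i * i for i in freqs) / (n * (n - 1))
            sims[r] = th_pi - th_H
    lower = (1 + int(np.sum(sims <= observed))) / (reps + 1)
    upper = (1 + int(np.sum(sims >= observed))) / (reps + 1)
    return {
        "statistic": stat, "observed": observed, "reps": reps, "seed": seed,
        "p_lower": lower, "p_upper": upper, "p": lower,
        "null_mean": float(np.mean(sims[np.isfinite(sims)])),
    }
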