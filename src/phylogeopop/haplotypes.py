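"""Aligned sequence handling: haplotype collapsing, genetic and geographic
distances, and the small-sample pooling filter.

Sequences are pre-aligned mtDNA/nDNA fragments over the alphabet
``{A, C, G, T, N, -}``.  ``N`` and ``-`` are treated as missing data and, by
default, excluded pairwise from all site comparisons.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

VALID_RESIDUES = frozenset("ACGTN-")
MISSING = frozenset("N-")
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

EARTH_RADIUS_KM = 6371.0


class AlignmentError(ValueError):
    """Sequences do not form a valid alignment."""


class InputError(ValueError):
    """Malformed input data."""


class UndefinedDistanceError(ValueError):
    """No comparable sites between a pair of sequences."""


@dataclass
class SequenceRecord:
    id: str
    sequence: str
    population: str | None = None

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        for pos, c in enumerate(self.sequence):
            if c not in VALID_RESIDUES:
                raise InputError(
                    f"record {self.id!r}: unknown residue {c!r} at position {pos + 1}"
                )


@dataclass
class SiteInfo:
    latitude: float
    longitude: float
    n: int


@dataclass
class HaplotypeAlignment:
    """An alignment with optional haplotype table and population metadata.

    ``haplotypes`` is a list of ``(sequence, count, member_ids)`` filled in by
    :func:`collapse_haplotypes`; ``populations`` maps a population label to a
    :class:`SiteInfo` (latitude/longitude in signed decimal degrees,
    east-positive).
    """

    records: list[SequenceRecord]
    haplotypes: list[tuple[str, int, list[str]]] = field(default_factory=list)
    populations: dict[str, SiteInfo] = field(default_factory=dict)
    pooling_warning: bool = False

    def __post_init__(self):
        if self.records:
            L = len(self.records[0].sequence)
            for r in self.records:
                if len(r.sequence) != L:
                    raise AlignmentError(
                        f"record {r.id!r} has length {len(r.sequence)}, expected {L}"
                    )
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise InputError(f"duplicate record ids: {dup}")

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def site_count(self) -> int:
        return len(self.records[0].sequence) if self.records else 0

    # alias used throughout the docs
    @property
    def L(self) -> int:
        return self.site_count

    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    def matrix(self) -> np.ndarray:
        """Alignment as an (n, L) byte matrix."""
        return np.frombuffer(
            "".join(r.sequence for r in self.records).encode(), dtype="S1"
        ).reshape(self.n, self.site_count)

    def population_of(self) -> dict[str, str | None]:
        return {r.id: r.population for r in self.records}

    def subset(self, ids: list[str]) -> "HaplotypeAlignment":
        wanted = set(ids)
        recs = [r for r in self.records if r.id in wanted]
        return HaplotypeAlignment(records=recs, populations=dict(self.populations))


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distance matrix with ordered labels."""

    labels: list[str]
    values: np.ndarray
    saturated_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.labels), len(self.labels)):
            raise InputError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise InputError("distance matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise InputError("distance matrix diagonal must be zero")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and finite.min() < 0:
            raise InputError("distances must be nonnegative")

    def __getitem__(self, pair):
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return self.values[i, j]

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def to_csv(self, path):
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow([""] + self.labels)
            for lab, row in zip(self.labels, self.values):
                w.writerow([lab] + [repr(float(v)) for v in row])

    @classmethod
    def from_csv(cls, path) -> "DistanceMatrix":
        with open(path, newline="") as fh:
            rows = list(csv.reader(fh))
        labels = rows[0][1:]
        values = np.array([[float(v) for v in r[1:]] for r in rows[1:]])
        return cls(labels=labels, values=values)


def read_site_table(path) -> dict[str, SiteInfo]:
    """Read a CSV with header ``population,lat,lon,n``."""
    sites: dict[str, SiteInfo] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            sites[row["population"]] = SiteInfo(
                latitude=float(row["lat"]),
                longitude=float(row["lon"]),
                n=int(row["n"]),
            )
    return sites


def write_site_table(sites: dict[str, SiteInfo], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["population", "lat", "lon", "n"])
        for pop, info in sites.items():
            w.writerow([pop, repr(info.latitude), repr(info.longitude), info.n])


def _population_from_id(rec_id: str, description: str) -> str | None:
    # convention: "pop|specimen" ids, or a "pop=NAME" token in the description
    for token in description.split():
        if token.startswith("pop="):
            return token[4:]
    if "|" in rec_id:
        return rec_id.split("|", 1)[0]
    return None


def read_fasta(path, site_table=None) -> HaplotypeAlignment:
    """Read an aligned FASTA (wrapped or single-line).

    Population labels are taken from a ``pop=NAME`` token in the description
    or from a ``pop|specimen`` id prefix; a site table CSV
    (``population,lat,lon,n``) supplies coordinates.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            SequenceRecord(
                id=rec.id,
                sequence=str(rec.seq),
                population=_population_from_id(rec.id, rec.description),
            )
        )
    if not records:
        raise InputError(f"no sequences found in {path}")
    populations = read_site_table(site_table) if site_table else {}
    return HaplotypeAlignment(records=records, populations=populations)


def write_fasta(aln: HaplotypeAlignment, path) -> None:
    with open(path, "w") as fh:
        for r in aln.records:
            fh.write(f">{r.id}\n{r.sequence}\n")


def _compatible(a: str, b: str) -> bool:
    """True when a and b agree at every site comparable in both."""
    return all(x == y or x in MISSING or y in MISSING for x, y in zip(a, b))


def collapse_haplotypes(
    aln: HaplotypeAlignment, missing_policy: str = "ignore_N"
) -> HaplotypeAlignment:
    """Collapse records into unique haplotypes.

    Under ``strict`` two sequences share a haplotype iff their strings are
    identical; under ``ignore_N`` sites missing in either member of a pair are
    excluded from the comparison (each record joins the first established
    haplotype whose representative it is compatible with).
    """
    if not aln.records:
        raise InputError("empty alignment")
    if missing_policy not in ("strict", "ignore_N"):
        raise InputError(f"unknown missing_policy {missing_policy!r}")

    haps: list[tuple[str, int, list[str]]] = []
    if missing_policy == "strict":
        index: dict[str, int] = {}
        for r in aln.records:
            if r.sequence in index:
                seq, cnt, members = haps[index[r.sequence]]
                haps[index[r.sequence]] = (seq, cnt + 1, members + [r.id])
            else:
                index[r.sequence] = len(haps)
                haps.append((r.sequence, 1, [r.id]))
    else:
        for r in aln.records:
            for k, (seq, cnt, members) in enumerate(haps):
                if _compatible(r.sequence, seq):
                    # keep the least-ambiguous representative
                    rep = seq if seq.count("N") + seq.count("-") <= (
                        r.sequence.count("N") + r.sequence.count("-")
                    ) else r.sequence
                    haps[k] = (rep, cnt + 1, members + [r.id])
                    break
            else:
                haps.append((r.sequence, 1, [r.id]))

    return HaplotypeAlignment(
        records=list(aln.records),
        haplotypes=haps,
        populations=dict(aln.populations),
        pooling_warning=aln.pooling_warning,
    )


def _comparable_mask(a: str, b: str):
    return [(x, y) for x, y in zip(a, b) if x not in MISSING and y not in MISSING]


def p_distance(a: str, b: str) -> float:
    """Uncorrected proportion of differing sites among comparable sites."""
    if len(a) != len(b):
        raise AlignmentError("sequences have different lengths")
    pairs = _comparable_mask(a.upper(), b.upper())
    if not pairs:
        raise UndefinedDistanceError("no comparable sites")
    mism = sum(x != y for x, y in pairs)
    return mism / len(pairs)


def n_differences(a: str, b: str) -> int:
    """Number of differing comparable sites (the AMOVA/mismatch metric)."""
    return sum(
        x != y
        for x, y in zip(a.upper(), b.upper())
        if x not in MISSING and y not in MISSING
    )


def pairwise_difference_matrix(aln: HaplotypeAlignment) -> np.ndarray:
    """(n, n) matrix of pairwise difference counts over comparable sites,
    computed by one-hot products (missing data excluded pairwise)."""
    M = aln.matrix()
    present = np.zeros(M.shape, dtype=np.float64)
    matches = np.zeros((aln.n, aln.n))
    for b in b"ACGT":
        X = (M == bytes([b])).astype(np.float64)
        present += X
        matches += X @ X.T
    comparable = present @ present.T
    D = comparable - matches
    np.fill_diagonal(D, 0.0)
    return D


def base_frequencies(aln: HaplotypeAlignment) -> dict[str, float]:
    """Empirical A/C/G/T frequencies over all non-missing alignment cells."""
    counts = {b: 0 for b in "ACGT"}
    for r in aln.records:
        for c in r.sequence:
            if c in counts:
                counts[c] += 1
    total = sum(counts.values())
    if total == 0:
        raise InputError("alignment contains no unambiguous bases")
    return {b: c / total for b, c in counts.items()}


def tamura_nei_distance(
    a: str, b: str, aln: HaplotypeAlignment | None = None,
    freqs: dict[str, float] | None = None,
) -> float:
    """TN93 distance; base frequencies from the whole alignment.

    Returns ``inf`` when a logarithm argument is nonpositive (saturation);
    matrix builders replace that signal per the saturation policy.
    """
    if freqs is None:
        if aln is None:
            freqs = {b: 0.25 for b in "ACGT"}
        else:
            freqs = base_frequencies(aln)
    pairs = _comparable_mask(a.upper(), b.upper())
    if not pairs:
        raise UndefinedDistanceError("no comparable sites")
    n = len(pairs)
    p1 = sum(1 for x, y in pairs if x != y and {x, y} <= PURINES) / n
    p2 = sum(1 for x, y in pairs if x != y and {x, y} <= PYRIMIDINES) / n
    q = sum(
        1 for x, y in pairs
        if x != y and ((x in PURINES) != (y in PURINES))
    ) / n

    gA, gC, gG, gT = (freqs[b] for b in "ACGT")
    gR, gY = gA + gG, gC + gT
    if min(gR, gY) <= 0 or gA * gG <= 0 or gC * gT <= 0:
        # degenerate composition: fall back to a Jukes-Cantor-style correction
        x = 1 - 4.0 * (p1 + p2 + q) / 3.0
        return math.inf if x <= 0 else -0.75 * math.log(x)

    k1 = 2 * gA * gG / gR
    k2 = 2 * gC * gT / gY
    k3 = 2 * (gR * gY - gA * gG * gY / gR - gC * gT * gR / gY)
    w1 = 1 - p1 / k1 - q / (2 * gR)
    w2 = 1 - p2 / k2 - q / (2 * gY)
    w3 = 1 - q / (2 * gR * gY)
    if w1 <= 0 or w2 <= 0 or w3 <= 0:
        return math.inf
    return -k1 * math.log(w1) - k2 * math.log(w2) - k3 * math.log(w3)


def distance_matrix(
    aln: HaplotypeAlignment, metric: str = "p", labels: list[str] | None = None
) -> DistanceMatrix:
    """Pairwise distances between records.

    ``metric``: ``p`` (proportion), ``tn93``, or ``differences`` (counts).
    TN93 saturation (infinite signal) is replaced by twice the largest finite
    distance and the pair recorded in ``saturated_pairs``.
    """
    seqs = aln.sequences()
    ids = labels if labels is not None else [r.id for r in aln.records]
    n = len(seqs)
    if metric == "differences":
        vals = pairwise_difference_matrix(aln)
    elif metric in ("p", "tn93"):
        vals = np.zeros((n, n))
        freqs = base_frequencies(aln) if metric == "tn93" else None
        for i in range(n):
            for j in range(i + 1, n):
                if metric == "p":
                    d = p_distance(seqs[i], seqs[j])
                else:
                    d = tamura_nei_distance(seqs[i], seqs[j], freqs=freqs)
                vals[i, j] = vals[j, i] = d
    else:
        raise InputError(f"unknown metric {metric!r}")

    saturated = []
    if metric == "tn93" and np.isinf(vals).any():
        finite_max = vals[np.isfinite(vals)].max()
        repl = 2.0 * finite_max if finite_max > 0 else 1.0
        for i, j in zip(*np.where(np.isinf(vals))):
            if i < j:
                saturated.append((ids[i], ids[j]))
        vals[np.isinf(vals)] = repl
        warnings.warn(
            f"{len(saturated)} saturated TN93 pair(s) capped at {repl:.6g}"
        )
    return DistanceMatrix(labels=ids, values=vals, saturated_pairs=saturated)


def great_circle_km(p1, p2) -> float:
    """Haversine great-circle distance in km (Earth radius 6371 km)."""
    lat1, lon1 = p1
    lat2, lon2 = p2
    for lat, lon in ((lat1, lon1), (lat2, lon2)):
        if abs(lat) > 90:
            raise InputError(f"latitude {lat} outside [-90, 90]")
        if abs(lon) > 180:
            raise InputError(f"longitude {lon} outside [-180, 180]")
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    h = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def pool_to_threshold(
    aln: HaplotypeAlignment, threshold: int = 8
) -> HaplotypeAlignment:
    """Merge each under-sampled population into its geographically nearest
    neighbour until every pool holds at least ``threshold`` samples.

    Merge order is smallest-N first, ties broken by label order.  Pool labels
    join member labels with ``+`` (sorted); pooled coordinates are the
    sample-size-weighted centroid.  If the total sample size is below the
    threshold a single pool is returned with ``pooling_warning`` set.
    """
    if not aln.populations:
        raise InputError("populations must be georeferenced before pooling")

    # current pools: label -> (member pops, lat, lon, n)
    pools = {
        pop: ([pop], info.latitude, info.longitude, info.n)
        for pop, info in aln.populations.items()
    }
    total_n = sum(p[3] for p in pools.values())
    warning = False
    if total_n < threshold:
        warning = True
        members = sorted(aln.populations)
        lat = sum(aln.populations[m].latitude * aln.populations[m].n for m in members) / total_n
        lon = sum(aln.populations[m].longitude * aln.populations[m].n for m in members) / total_n
        pools = {"+".join(members): (members, lat, lon, total_n)}
    else:
        while True:
            small = sorted(
                (lab for lab, p in pools.items() if p[3] < threshold),
                key=lambda lab: (pools[lab][3], lab),
            )
            if not small or len(pools) == 1:
                break
            lab = small[0]
            mem, lat, lon, n = pools[lab]
            nearest = min(
                (o for o in pools if o != lab),
                key=lambda o: (great_circle_km((lat, lon), pools[o][1:3]), o),
            )
            mem2, lat2, lon2, n2 = pools.pop(nearest)
            pools.pop(lab)
            allmem = sorted(mem + mem2)
            nm = n + n2
            pools["+".join(allmem)] = (
                allmem,
                (lat * n + lat2 * n2) / nm,
                (lon * n + lon2 * n2) / nm,
                nm,
            )

    pop_of = {}
    for lab, (mem, _, _, _) in pools.items():
        for m in mem:
            pop_of[m] = lab
    new_records = [
        SequenceRecord(
            id=r.id,
            sequence=r.sequence,
            population=pop_of.get(r.population, r.population),
        )
        for r in aln.records
    ]
    new_pops = {
        lab: SiteInfo(latitude=lat, longitude=lon, n=n)
        for lab, (_, lat, lon, n) in pools.items()
    }
    return HaplotypeAlignment(
        records=new_records, populations=new_pops, pooling_warning=warning
    )
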