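"""Homozygosity-deficit haplotype scan.

Window haplotypes from phased genotypes are tested for a deficit of
homozygous animals relative to the Hardy-Weinberg expectation ``E = N q^2``
with a one-sided lower-tail exact binomial test, Bonferroni-corrected over
all haplotypes actually tested.  Adjacent significant windows are merged into
candidate regions harbouring a putative recessive lethal.

Also houses the marker/animal quality-control filters applied upstream of
phasing: minor allele frequency, call rates, and a Hardy-Weinberg exact test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import PhasedGenotypes

DEFAULT_WINDOW_SIZES = (1_000_000, 2_000_000)


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------


def hwe_exact_test(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact Hardy-Weinberg test p-value for one diallelic marker.

    Sums the probabilities of all heterozygote counts (conditional on allele
    counts) no more likely than the observed one — the standard exact HWE
    test used by genotype-QC tools.
    """
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    n_rare = n_het + 2 * min(n_hom1, n_hom2)

    def log_prob(h: int) -> float:
        # P(het = h | allele counts) up to a shared constant
        rare_hom = (n_rare - h) // 2
        common_hom = n - h - rare_hom
        return (h * math.log(2)
                - math.lgamma(h + 1) - math.lgamma(rare_hom + 1)
                - math.lgamma(common_hom + 1))

    hets = range(n_rare % 2, n_rare + 1, 2)
    logs = np.array([log_prob(h) for h in hets])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    obs = probs[list(hets).index(n_het)]
    return float(min(1.0, probs[probs <= obs * (1 + 1e-12)].sum()))


def apply_qc_filters(geno: np.ndarray, markers: pd.DataFrame,
                     animal_ids: list[str] | None = None, *,
                     min_maf: float = 0.01,
                     min_marker_call_rate: float = 0.90,
                     min_animal_call_rate: float = 0.70,
                     hwe_min_p: float = 1e-8,
                     ) -> tuple[np.ndarray, pd.DataFrame, list[str], dict]:
    """Filter an unphased genotype table (N x M, values 0/1/2, -1 missing).

    Animals with call rate <= ``min_animal_call_rate`` are removed first;
    marker filters (MAF, call rate, HWE) are then applied on the surviving
    animals.  Thresholds are strict: a marker is kept only if MAF > 1%,
    call rate > 90% and HWE exact p >= 1e-8 at the defaults.

    Returns (filtered genotypes, filtered markers, surviving animal ids,
    report of per-filter removal counts).  Raises if nothing survives.
    """
    geno = np.asarray(geno)
    n, m = geno.shape
    if animal_ids is None:
        animal_ids = [f"S{i + 1}" for i in range(n)]
    called = geno >= 0

    animal_call = called.mean(axis=1)
    keep_animals = animal_call > min_animal_call_rate
    geno = geno[keep_animals]
    called = called[keep_animals]
    surviving = [a for a, k in zip(animal_ids, keep_animals) if k]

    with np.errstate(invalid="ignore"):
        marker_call = called.mean(axis=0)
        alt_freq = np.where(called, geno, 0).sum(axis=0) / (2.0 * called.sum(axis=0))
    maf = np.minimum(alt_freq, 1 - alt_freq)
    keep_call = marker_call > min_marker_call_rate
    keep_maf = np.nan_to_num(maf) > min_maf

    hwe_p = np.ones(geno.shape[1])
    for j in range(geno.shape[1]):
        col = geno[called[:, j], j]
        hwe_p[j] = hwe_exact_test(int((col == 1).sum()), int((col == 0).sum()),
                                  int((col == 2).sum()))
    keep_hwe = hwe_p >= hwe_min_p

    keep_markers = keep_call & keep_maf & keep_hwe
    report = {
        "animals_removed_call_rate": int((~keep_animals).sum()),
        "markers_removed_call_rate": int((~keep_call).sum()),
        "markers_removed_maf": int((keep_call & ~keep_maf).sum()),
        "markers_removed_hwe": int((keep_call & keep_maf & ~keep_hwe).sum()),
        "animals_kept": len(surviving),
        "markers_kept": int(keep_markers.sum()),
    }
    if len(surviving) == 0 or report["markers_kept"] == 0:
        raise ValueError(f"QC removed all animals or markers: {report}")
    return (geno[:, keep_markers], markers[keep_markers].reset_index(drop=True),
            surviving, report)


# ---------------------------------------------------------------------------
# Windows and haplotype counting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Window:
    chrom: str
    start: int  # bp, half-open [start, end)
    end: int
    size: int
    marker_idx: tuple[int, ...]


def enumerate_windows(markers: pd.DataFrame,
                      sizes: tuple[int, ...] = DEFAULT_WINDOW_SIZES,
                      step: int | None = None) -> list[Window]:
    """Overlapping sliding windows per chromosome and size class.

    Windows start at the chromosome's first marker position and advance by
    ``step`` (default: half the window size) while the start does not pass
    the last marker; windows covering fewer than 2 markers are dropped.
    Boundaries are half-open: a marker at ``pos == end`` is excluded.
    """
    if step is not None and step <= 0:
        raise ValueError("step must be positive")
    windows: list[Window] = []
    for chrom, sub in markers.groupby("chrom", sort=False):
        pos = sub["pos_bp"].to_numpy()
        idx = sub.index.to_numpy()
        first, last = int(pos[0]), int(pos[-1])
        for size in sizes:
            this_step = step if step is not None else size // 2
            start = first
            while start <= last:
                in_win = (pos >= start) & (pos < start + size)
                if in_win.sum() >= 2:
                    windows.append(Window(str(chrom), start, start + int(size),
                                          int(size), tuple(idx[in_win])))
                start += this_step
    return windows


@dataclass
class HaplotypeRecord:
    """One window haplotype with its homozygosity-deficit statistics."""

    window: Window
    alleles: str                 # e.g. "0110...", window-marker allele string
    count: int                   # haplotype copies k among 2N chromosomes
    freq: float                  # q = k / 2N
    het_carriers: int
    carrier_freq: float          # heterozygous animals / N
    obs_hom: int
    exp_hom: float               # N * q^2
    p_value: float
    p_adj: float = 1.0
    significant: bool = False
    carrier_ids: tuple[str, ...] = field(default=(), repr=False)
    hom_ids: tuple[str, ...] = field(default=(), repr=False)

    @property
    def chrom(self) -> str:
        return self.window.chrom


def count_window_haplotypes(phased: PhasedGenotypes, window: Window,
                            min_count: int = 1) -> list[HaplotypeRecord]:
    """Tally the 2N chromosome strings over one window's markers.

    An animal is homozygous for a haplotype iff both its strings equal it;
    a heterozygous carrier iff exactly one does.  Counts sum to 2N.
    Haplotypes with fewer than ``min_count`` copies are not reported
    (a cheap pre-filter for the scan's frequency threshold).
    """
    idx = np.asarray(window.marker_idx)
    if len(idx) == 0:
        raise ValueError("window contains no markers")
    strings = phased.chromosome_strings(idx)
    uniq, inverse = np.unique(strings, axis=0, return_inverse=True)
    codes = inverse.reshape(-1, 2)  # (N, 2)
    n = phased.n_animals
    k = np.bincount(inverse, minlength=len(uniq))
    hom_mask = codes[:, 0] == codes[:, 1]
    hom = np.bincount(codes[hom_mask, 0], minlength=len(uniq))
    # copies per haplotype split into het and hom animals: k = het + 2*hom
    het = k - 2 * hom

    records = []
    ids = np.asarray(phased.animal_ids)
    for h in range(len(uniq)):
        if k[h] < min_count:
            continue
        q = k[h] / (2.0 * n)
        carrier_mask = (codes[:, 0] == h) | (codes[:, 1] == h)
        records.append(HaplotypeRecord(
            window=window,
            alleles="".join(map(str, uniq[h].tolist())),
            count=int(k[h]), freq=float(q),
            het_carriers=int(het[h]), carrier_freq=float(het[h] / n),
            obs_hom=int(hom[h]), exp_hom=expected_homozygotes(q, n),
            p_value=deficit_binomial_test(int(hom[h]), n, float(q)),
            carrier_ids=tuple(ids[carrier_mask].tolist()),
            hom_ids=tuple(ids[hom_mask & (codes[:, 0] == h)].tolist()),
        ))
    return records


# ---------------------------------------------------------------------------
# Deficit statistics
# ---------------------------------------------------------------------------


def expected_homozygotes(q: float, n: int) -> float:
    """Hardy-Weinberg expected homozygote count, ``N * q**2``."""
    if not 0 <= q <= 1:
        raise ValueError("haplotype frequency must be in [0, 1]")
    if n < 0:
        raise ValueError("N must be non-negative")
    return n * q * q


def haplotype_freq_from_carrier_freq(c: float) -> float:
    """Solve ``c = 2 q (1 - q)`` for the minor root q given carrier frequency c."""
    if not 0 <= c <= 0.5:
        raise ValueError("heterozygous-carrier frequency must be in [0, 0.5]")
    return (1.0 - math.sqrt(1.0 - 2.0 * c)) / 2.0


def deficit_binomial_test(obs_hom: int, n: int, q: float) -> float:
    """One-sided lower-tail exact binomial p-value, X ~ Binomial(N, q^2).

    Only a deficit of homozygotes is biologically meaningful for a recessive
    lethal, so the upper tail is not tested.  ``P(X <= O)``; returns 1 when
    the expectation is zero or the observation exhausts the sample.
    """
    if not 0 <= obs_hom <= n:
        raise ValueError("observed homozygotes must be in [0, N]")
    if not 0 <= q <= 1:
        raise ValueError("haplotype frequency must be in [0, 1]")
    if q == 0 or obs_hom == n:
        return 1.0
    p = float(stats.binom.cdf(obs_hom, n, q * q))
    # keep p in (0, 1]; exactly 0 only arises in the degenerate q = 1 case
    return min(1.0, max(p, 5e-324))


def scan(phased: PhasedGenotypes, *,
         min_haplotype_freq: float = 0.005,
         max_obs_hom: int = 30,
         alpha: float = 0.05,
         window_sizes: tuple[int, ...] = DEFAULT_WINDOW_SIZES,
         step: int | None = None) -> list[HaplotypeRecord]:
    """Scan all window haplotypes for homozygote deficiency.

    Haplotypes with frequency > ``min_haplotype_freq`` (guarding against
    phasing artefacts and powerless rare strings) and at most ``max_obs_hom``
    observed homozygotes are tested; the Bonferroni denominator is the number
    of haplotypes actually tested across both window sizes.  Output sorted by
    adjusted p-value.
    """
    windows = enumerate_windows(phased.markers, sizes=window_sizes, step=step)
    # q > threshold  <=>  k >= floor(2N * threshold) + 1
    min_count = int(2 * phased.n_animals * min_haplotype_freq) + 1
    tested: list[HaplotypeRecord] = []
    for window in windows:
        for rec in count_window_haplotypes(phased, window, min_count=min_count):
            if rec.freq > min_haplotype_freq and rec.obs_hom <= max_obs_hom:
                tested.append(rec)
    m = len(tested)
    for rec in tested:
        rec.p_adj = min(1.0, m * rec.p_value)
        rec.significant = rec.p_adj < alpha
    tested.sort(key=lambda r: (r.p_adj, r.p_value, r.chrom, r.window.start, r.alleles))
    return tested


# ---------------------------------------------------------------------------
# Regions and carrier status
# ---------------------------------------------------------------------------


@dataclass
class Region:
    """Merged run of overlapping/adjacent significant windows on one chromosome."""

    chrom: str
    start: int
    end: int
    records: list[HaplotypeRecord]

    @property
    def representative(self) -> HaplotypeRecord:
        return min(self.records, key=lambda r: (r.p_adj, r.p_value, r.window.start))

    @property
    def carriers(self) -> set[str]:
        out: set[str] = set()
        for rec in self.records:
            out.update(rec.carrier_ids)
        return out


def merge_significant_windows(records: list[HaplotypeRecord]) -> list[Region]:
    """Merge significant window haplotypes that overlap or abut on a chromosome."""
    sig = [r for r in records if r.significant]
    regions: list[Region] = []
    by_chrom: dict[str, list[HaplotypeRecord]] = {}
    for rec in sig:
        by_chrom.setdefault(rec.chrom, []).append(rec)
    for chrom in sorted(by_chrom):
        recs = sorted(by_chrom[chrom], key=lambda r: (r.window.start, r.window.end))
        current: Region | None = None
        for rec in recs:
            if current is not None and rec.window.start <= current.end:
                current.end = max(current.end, rec.window.end)
                current.records.append(rec)
            else:
                current = Region(chrom, rec.window.start, rec.window.end, [rec])
                regions.append(current)
    return regions


CARRIER_STATUSES = ("non-carrier", "carrier", "homozygous", "unknown")


def assign_carrier_status(phased: PhasedGenotypes, region: Region,
                          all_animals: list[str] | None = None) -> pd.DataFrame:
    """Per-animal status against the region's representative haplotype.

    Both chromosome strings match -> homozygous; exactly one -> carrier;
    none -> non-carrier.  Animals listed in ``all_animals`` but absent from
    the genotype data are reported as unknown.
    """
    rep = region.representative
    idx = np.asarray(rep.window.marker_idx)
    target = np.frombuffer("".join(rep.alleles).encode(), dtype=np.uint8) - ord("0")
    strings = phased.chromosome_strings(idx).reshape(phased.n_animals, 2, -1)
    matches = (strings == target[None, None, :]).all(axis=2).sum(axis=1)
    status = np.array(CARRIER_STATUSES)[matches]
    table = pd.DataFrame({"animal_id": phased.animal_ids, "status": status})
    if all_animals is not None:
        extra = [a for a in all_animals if a not in set(phased.animal_ids)]
        if extra:
            table = pd.concat([table, pd.DataFrame(
                {"animal_id": extra, "status": "unknown"})], ignore_index=True)
    return table


def records_to_frame(records: list[HaplotypeRecord]) -> pd.DataFrame:
    """Flatten scan output to a table mirroring the published summary columns."""
    return pd.DataFrame([{
        "chrom": r.chrom,
        "start_bp": r.window.start,
        "end_bp": r.window.end,
        "window_size": r.window.size,
        "alleles": r.alleles,
        "count": r.count,
        "freq": r.freq,
        "carrier_freq": r.carrier_freq,
        "obs_hom": r.obs_hom,
        "exp_hom": r.exp_hom,
        "p_value": r.p_value,
        "p_adj": r.p_adj,
        "significant": r.significant,
    } for r in records])
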