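"""Candidate causal variant prioritization from sequenced-carrier concordance.

A variant near a homozygosity-deficient region is a candidate causal lethal
when (i) it lies within a margin (default 4 Mb) of the region boundaries,
(ii) every sequenced haplotype-carrier sire is heterozygous for it and at
most one sequenced sire is homozygous for the alternate allele, and (iii) at
most three sequenced non-carrier sires carry the allele.  Survivors are
triaged by predicted consequence (loss-of-function > deleterious missense >
tolerated/other) and demoted on external evidence (known homozygotes in
variant databases, non-conserved sites).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import pysam

GT_HOM_REF, GT_HET, GT_HOM_ALT, GT_MISSING = 0, 1, 2, -1

#: consequence classes presumed to abolish protein function
LOF_CLASSES = frozenset({
    "frameshift", "stop_gained", "stop_lost", "start_lost",
    "splice_donor", "splice_acceptor", "inframe_insertion", "inframe_deletion",
})

TIERS = ("LoF", "deleterious-missense", "tolerated", "other")


@dataclass
class VariantRecord:
    """One sequenced-sire variant with genotypes and consequence annotation."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    var_class: str = "SNP"  # SNP | indel | SV
    sv_end: int | None = None
    consequence: str = ""
    sift: float | None = None
    known_homozygote: bool = False
    non_conserved: bool = False
    genotypes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.var_class == "SV" and (self.sv_end is None or self.sv_end <= self.pos):
            raise ValueError("SV records need sv_end > pos")
        if self.sift is not None and not 0 <= self.sift <= 1:
            raise ValueError("SIFT score must be in [0, 1]")

    @property
    def span(self) -> tuple[int, int]:
        return self.pos, self.sv_end if self.sv_end is not None else self.pos + len(self.ref)


@dataclass
class CandidateVariant:
    """Concordance-filter survivor with its per-criterion audit trail."""

    variant: VariantRecord
    n_carriers_het: int
    n_carriers_total: int
    n_hom_alt: int
    n_noncarriers_with_allele: int
    pass_position: bool
    pass_carrier_het: bool
    pass_noncarrier: bool
    tier: str = "other"

    @property
    def pass_all(self) -> bool:
        return self.pass_position and self.pass_carrier_het and self.pass_noncarrier


def concordance_filter(variants: list[VariantRecord],
                       carrier_flags: dict[str, bool],
                       region_chrom: str, region_start: int, region_end: int, *,
                       margin: int = 4_000_000,
                       max_hom: int = 1,
                       max_noncarrier: int = 3,
                       min_carriers: int = 2) -> list[CandidateVariant]:
    """Apply the three carrier-concordance criteria to a region's variants.

    ``carrier_flags`` maps each sequenced sire to its carrier status for this
    region; a missing genotype in a carrier fails criterion (ii)
    conservatively, and homozygous-alternate counts are taken over all
    sequenced sires.  Raises if fewer than ``min_carriers`` sequenced
    carriers exist (too little information to fine-map the region).
    """
    carriers = sorted(s for s, f in carrier_flags.items() if f)
    noncarriers = sorted(s for s, f in carrier_flags.items() if not f)
    if len(carriers) < min_carriers:
        raise ValueError(
            f"region {region_chrom}:{region_start}-{region_end} has "
            f"{len(carriers)} sequenced carriers (< {min_carriers}); skipped")

    lo, hi = region_start - margin, region_end + margin
    out: list[CandidateVariant] = []
    for v in variants:
        pass_pos = v.chrom == region_chrom and lo <= v.pos < hi
        het = sum(1 for s in carriers if v.genotypes.get(s, GT_MISSING) == GT_HET)
        hom = sum(1 for g in (v.genotypes.get(s, GT_MISSING)
                              for s in carriers + noncarriers) if g == GT_HOM_ALT)
        nc_with = sum(1 for s in noncarriers
                      if v.genotypes.get(s, GT_MISSING) in (GT_HET, GT_HOM_ALT))
        pass_het = het == len(carriers) and hom <= max_hom
        pass_nc = nc_with <= max_noncarrier
        cand = CandidateVariant(
            variant=v, n_carriers_het=het, n_carriers_total=len(carriers),
            n_hom_alt=hom, n_noncarriers_with_allele=nc_with,
            pass_position=pass_pos, pass_carrier_het=pass_het, pass_noncarrier=pass_nc)
        if cand.pass_all:
            out.append(cand)
    out.sort(key=lambda c: (c.variant.chrom, c.variant.pos, c.variant.alt))
    return out


def classify_consequence(variant: VariantRecord, *,
                         sift_threshold: float = 0.05,
                         exons: list[tuple[str, int, int]] | None = None) -> str:
    """Assign a consequence tier.

    LoF: any loss-of-function class, or an SV overlapping >= 1 bp of an exon;
    missense splits on the SIFT threshold (<= 0.05 deleterious); missense
    without a SIFT score falls to "other" with a warning rather than being
    silently treated as deleterious.
    """
    cons = variant.consequence.lower().replace(" ", "_").replace("&", ",")
    terms = {t.strip() for part in cons.split(",") for t in part.split("|")}
    if variant.var_class == "SV":
        start, end = variant.span
        for chrom, ex_start, ex_end in exons or []:
            if chrom == variant.chrom and start < ex_end and ex_start < end:
                return "LoF"
        return "other"
    if terms & LOF_CLASSES:
        return "LoF"
    if "missense" in terms or "missense_variant" in terms:
        if variant.sift is None:
            warnings.warn(
                f"missense variant {variant.chrom}:{variant.pos} lacks a SIFT "
                "score; classified 'other'", stacklevel=2)
            return "other"
        return "deleterious-missense" if variant.sift <= sift_threshold else "tolerated"
    return "other"


def rank_candidates(candidates: list[CandidateVariant], *,
                    sift_threshold: float = 0.05,
                    exons: list[tuple[str, int, int]] | None = None
                    ) -> list[CandidateVariant]:
    """Order candidates LoF first, demoting database-homozygote or
    non-conserved variants within each tier; ties break on genomic coordinate."""
    for cand in candidates:
        cand.tier = classify_consequence(cand.variant, sift_threshold=sift_threshold,
                                         exons=exons)
    tier_rank = {"LoF": 0, "deleterious-missense": 1, "tolerated": 2, "other": 2}
    return sorted(candidates, key=lambda c: (
        tier_rank[c.tier],
        bool(c.variant.known_homozygote or c.variant.non_conserved),
        c.variant.chrom, c.variant.pos, c.variant.alt))


@dataclass
class DiscordanceReport:
    """Haplotype/variant concordance among animals with both calls."""

    hap_hom_not_var_hom: list[str]  # putative recombinants
    hap_het_var_hom: list[str]
    n_compared: int
    n_concordant: int

    @property
    def concordance(self) -> float:
        return self.n_concordant / self.n_compared if self.n_compared else float("nan")


def check_haplotype_variant_discordance(carrier_status,
                                        variant_genotypes: dict[str, int]
                                        ) -> DiscordanceReport:
    """Compare per-animal haplotype status with candidate-variant genotypes.

    Animals homozygous for the haplotype but not homozygous-alternate for the
    variant are putative recombinants (the haplotype-based carrier call is
    not fully reliable); the converse mismatch is also listed.  Animals with
    a missing variant genotype are excluded from the denominator.
    """
    if isinstance(carrier_status, pd.DataFrame):
        status = dict(zip(carrier_status["animal_id"], carrier_status["status"]))
    else:
        status = dict(carrier_status)
    shared = [a for a in status
              if variant_genotypes.get(a, GT_MISSING) != GT_MISSING]
    hap_hom_not_var_hom = [a for a in shared if status[a] == "homozygous"
                           and variant_genotypes[a] != GT_HOM_ALT]
    hap_het_var_hom = [a for a in shared if status[a] == "carrier"
                       and variant_genotypes[a] == GT_HOM_ALT]
    expected = {"homozygous": GT_HOM_ALT, "carrier": GT_HET,
                "non-carrier": GT_HOM_REF}
    compared = [a for a in shared if status[a] in expected]
    concordant = sum(1 for a in compared
                     if variant_genotypes[a] == expected[status[a]])
    return DiscordanceReport(sorted(hap_hom_not_var_hom), sorted(hap_het_var_hom),
                             len(compared), concordant)


# ---------------------------------------------------------------------------
# File IO
# ---------------------------------------------------------------------------


def read_variant_vcf(path: str | Path, *,
                     consequence_key: str = "CSQ") -> list[VariantRecord]:
    """Read sequenced-sire variants from a VCF.

    Small variants carry their consequence string in ``consequence_key``
    (dialect: ``gene|class|aa_change``); SVs are recognized by the SVTYPE
    INFO key with END giving the interval.  Optional annotations: SIFT
    (float), KNOWN_HOM and NONCONS (flags).
    """
    out: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            if rec.alts is None:
                continue
            info = dict(rec.info)
            svtype = info.get("SVTYPE")
            gts: dict[str, int] = {}
            for s in samples:
                gt = rec.samples[s]["GT"]
                if gt is None or None in gt:
                    gts[s] = GT_MISSING
                else:
                    gts[s] = int(sum(1 for a in gt if a and a > 0))
            cons = info.get(consequence_key, "")
            if isinstance(cons, tuple):
                cons = ",".join(cons)
            sift = info.get("SIFT")
            if isinstance(sift, tuple):
                sift = sift[0]
            ref, alt = rec.ref, rec.alts[0]
            if svtype:
                var_class = "SV"
            elif len(ref) != len(alt):
                var_class = "indel"
            else:
                var_class = "SNP"
            out.append(VariantRecord(
                chrom=str(rec.chrom), pos=rec.pos, ref=ref, alt=alt,
                var_class=var_class,
                sv_end=int(info["END"]) if svtype and "END" in info else
                (rec.stop if svtype else None),
                consequence=str(cons), sift=float(sift) if sift is not None else None,
                known_homozygote=bool(info.get("KNOWN_HOM", False)),
                non_conserved=bool(info.get("NONCONS", False)),
                genotypes=gts))
    return out


def read_exons(path: str | Path) -> list[tuple[str, int, int]]:
    """Read exon intervals from BED (0-based half-open) or GFF3 (1-based).

    Returned intervals are half-open (start, end) on a 1-based coordinate
    axis, matching :class:`VariantRecord` spans.
    """
    path = Path(path)
    exons: list[tuple[str, int, int]] = []
    if path.suffix.lower() in (".gff", ".gff3"):
        tab = pd.read_csv(path, sep="\t", comment="#", header=None,
                          names=["chrom", "source", "type", "start", "end",
                                 "score", "strand", "frame", "attrs"],
                          dtype={"chrom": str})
        tab = tab[tab["type"] == "exon"]
        for row in tab.itertuples(index=False):
            exons.append((str(row.chrom), int(row.start), int(row.end) + 1))
    else:
        tab = pd.read_csv(path, sep="\t", comment="#", header=None,
                          usecols=[0, 1, 2], names=["chrom", "start", "end"],
                          dtype={"chrom": str})
        for row in tab.itertuples(index=False):
            exons.append((str(row.chrom), int(row.start) + 1, int(row.end) + 1))
    return exons


def candidates_to_frame(candidates: list[CandidateVariant]) -> pd.DataFrame:
    return pd.DataFrame([{
        "chrom": c.variant.chrom,
        "pos": c.variant.pos,
        "ref": c.variant.ref,
        "alt": c.variant.alt,
        "class": c.variant.var_class,
        "tier": c.tier,
        "consequence": c.variant.consequence,
        "sift": c.variant.sift,
        "n_carriers_het": c.n_carriers_het,
        "n_carriers_total": c.n_carriers_total,
        "n_hom_alt": c.n_hom_alt,
        "n_noncarriers_with_allele": c.n_noncarriers_with_allele,
        "known_homozygote": c.variant.known_homozygote,
        "non_conserved": c.variant.non_conserved,
    } for c in candidates])
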