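"""Phased genotype container and chip-format IO (phased VCF + marker map).

The scan operates on a dense, complete matrix of phased diallelic calls.
Markers are described by a PLINK-BIM-style table with 1-based physical
positions, strictly increasing within a chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

MAP_COLUMNS = ["chrom", "marker_id", "pos_bp", "allele1", "allele2"]


class UnphasedInputError(ValueError):
    """Raised when a genotype source contains unphased or missing calls."""


def validate_marker_map(markers: pd.DataFrame) -> None:
    """Check marker-map invariants: required columns, unique ids, sorted positions."""
    missing = [c for c in MAP_COLUMNS if c not in markers.columns]
    if missing:
        raise ValueError(f"marker map missing columns: {missing}")
    if markers["marker_id"].duplicated().any():
        raise ValueError("marker ids are not unique")
    for chrom, sub in markers.groupby("chrom", sort=False):
        pos = sub["pos_bp"].to_numpy()
        if not np.all(np.diff(pos) > 0):
            raise ValueError(f"positions not strictly increasing on chromosome {chrom}")


@dataclass
class PhasedGenotypes:
    """N animals x M markers x 2 phased allele calls, entries in {0, 1}.

    ``alleles[:, :, 0]`` is the paternally derived chromosome copy when the
    data come from the gene-drop simulator; for data read from a VCF the two
    copies are simply the two phased alleles in file order.
    """

    animal_ids: list[str]
    alleles: np.ndarray  # (N, M, 2) uint8
    markers: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        if self.alleles.ndim != 3 or self.alleles.shape[2] != 2:
            raise ValueError("allele matrix must have shape (N, M, 2)")
        n, m, _ = self.alleles.shape
        if n != len(self.animal_ids):
            raise ValueError("animal_ids length does not match allele matrix")
        if m != len(self.markers):
            raise ValueError("marker map length does not match allele matrix")
        if n == 0 or m < 2:
            raise ValueError("need at least one animal and two markers")
        if self.alleles.max(initial=0) > 1:
            raise ValueError("allele calls must be 0/1 (diallelic, no missing)")
        validate_marker_map(self.markers)

    @property
    def n_animals(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_markers(self) -> int:
        return self.alleles.shape[1]

    def chromosome_strings(self, marker_idx: np.ndarray) -> np.ndarray:
        """Return the 2N haplotype strings over ``marker_idx`` as a (2N, m) array.

        Rows alternate copy 0 / copy 1 per animal: row 2i is animal i copy 0.
        """
        sub = self.alleles[:, marker_idx, :]  # (N, m, 2)
        return np.ascontiguousarray(sub.transpose(0, 2, 1).reshape(-1, len(marker_idx)))

    def subset_animals(self, keep: np.ndarray) -> "PhasedGenotypes":
        ids = [self.animal_ids[i] for i in np.flatnonzero(np.asarray(keep))] \
            if np.asarray(keep).dtype == bool else [self.animal_ids[i] for i in keep]
        idx = np.flatnonzero(keep) if np.asarray(keep).dtype == bool else np.asarray(keep)
        return PhasedGenotypes(ids, self.alleles[idx], self.markers)


def write_marker_map(markers: pd.DataFrame, path: str | Path) -> None:
    validate_marker_map(markers)
    markers[MAP_COLUMNS].to_csv(path, sep="\t", index=False)


def read_marker_map(path: str | Path) -> pd.DataFrame:
    markers = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    validate_marker_map(markers)
    return markers


def write_haplotype_table(phased: PhasedGenotypes, path: str | Path) -> None:
    """Write one row per chromosome copy: animal_id, copy, then marker alleles."""
    strings = phased.chromosome_strings(np.arange(phased.n_markers))
    frame = pd.DataFrame(strings, columns=phased.markers["marker_id"])
    frame.insert(0, "copy", np.tile([0, 1], phased.n_animals))
    frame.insert(0, "animal_id", np.repeat(phased.animal_ids, 2))
    frame.to_csv(path, sep="\t", index=False)


def read_haplotype_table(path: str | Path, markers: pd.DataFrame) -> PhasedGenotypes:
    """Read a plain haplotype table (two rows per animal) against a marker map."""
    frame = pd.read_csv(path, sep="\t", dtype={"animal_id": str})
    validate_marker_map(markers)
    marker_cols = list(markers["marker_id"])
    missing = [m for m in marker_cols if m not in frame.columns]
    if missing:
        raise ValueError(f"haplotype table lacks markers: {missing[:5]}")
    frame = frame.sort_values(["animal_id", "copy"], kind="stable")
    counts = frame["animal_id"].value_counts()
    if (counts != 2).any():
        raise ValueError("each animal needs exactly two chromosome rows")
    animals = frame["animal_id"].iloc[::2].tolist()
    values = frame[marker_cols].to_numpy(dtype=np.uint8)
    alleles = values.reshape(len(animals), 2, -1).transpose(0, 2, 1)
    return PhasedGenotypes(animals, alleles, markers)


def write_vcf(phased: PhasedGenotypes, path: str | Path) -> None:
    """Write phased genotypes as an uncompressed VCF with '|'-separated GT calls."""
    markers = phased.markers
    header = pysam.VariantHeader()
    header.add_meta("source", "hapdeficit")
    for chrom, sub in markers.groupby("chrom", sort=False):
        header.contigs.add(str(chrom), length=int(sub["pos_bp"].max()) + 1)
    header.formats.add("GT", 1, "String", "Genotype")
    for animal in phased.animal_ids:
        header.add_sample(str(animal))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j in range(phased.n_markers):
            row = markers.iloc[j]
            rec = out.new_record(
                contig=str(row["chrom"]),
                start=int(row["pos_bp"]) - 1,  # pysam start is 0-based
                alleles=(str(row["allele1"]), str(row["allele2"])),
                id=str(row["marker_id"]),
            )
            col = phased.alleles[:, j, :]
            for i, animal in enumerate(phased.animal_ids):
                sample = rec.samples[animal]
                sample["GT"] = (int(col[i, 0]), int(col[i, 1]))
                sample.phased = True
            out.write(rec)


def read_vcf(path: str | Path) -> PhasedGenotypes:
    """Read a phased diallelic VCF into a :class:`PhasedGenotypes`.

    Raises :class:`UnphasedInputError` on any unphased or missing genotype —
    the scan assumes a post-phasing dataset with complete calls.
    """
    rows = []
    columns = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(f"marker {rec.id} is not diallelic")
            rows.append((str(rec.chrom), rec.id or f"{rec.chrom}:{rec.pos}",
                         rec.pos, rec.ref, rec.alts[0]))
            col = np.empty((len(samples), 2), dtype=np.uint8)
            for i, s in enumerate(samples):
                sample = rec.samples[s]
                gt = sample["GT"]
                if gt is None or None in gt or len(gt) != 2 or not sample.phased:
                    raise UnphasedInputError(
                        f"unphased or missing genotype at {rec.chrom}:{rec.pos} sample {s}")
                col[i] = gt
            columns.append(col)
    if not columns:
        raise ValueError("VCF contains no records")
    markers = pd.DataFrame(rows, columns=MAP_COLUMNS)
    alleles = np.stack(columns, axis=1)  # (N, M, 2)
    return PhasedGenotypes(samples, alleles, markers)
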