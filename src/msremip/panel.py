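"""Panel data model: MSRE enzymes, target regions, smMIPs, selection rules.

The assay digests genomic DNA with four methylation-sensitive restriction
enzymes (MSREs) whose 4-bp recognition motifs each carry a central CpG:
HpaII (CCGG), HpyCH4IV (ACGT), AciI (CCGC) and HinP1I (GCGC).  An
unmethylated recognition site is cleaved and the fragment is lost; a
methylated CpG blocks the enzyme so the fragment survives and can be
captured by a single-molecule molecular inversion probe (smMIP).

This module scans sequences for recognition sites, applies the CpG-target
and reference-region selection rules, and models the panel (targets +
smMIPs) with TSV/FASTA/BED round-trips.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .matrix import (
    CATEGORIES,
    CATEGORY_CPG,
    CATEGORY_LAMBDA_CPG,
    CATEGORY_LAMBDA_REF,
    CATEGORY_REF_NO_CPG,
    CATEGORY_REF_NO_SITE,
)

_DNA = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MsreEnzyme:
    """A methylation-sensitive restriction enzyme with a 4-bp motif."""

    name: str
    motif: str

    def __post_init__(self) -> None:
        if len(self.motif) != 4:
            raise ValueError(f"{self.name}: motif must be 4 bp, got {self.motif!r}")
        if "CG" not in (self.motif[1:3],):
            raise ValueError(f"{self.name}: motif must carry a central CpG, got {self.motif!r}")

    @property
    def is_palindromic(self) -> bool:
        return reverse_complement(self.motif) == self.motif


#: The four enzymes used by the assay.
DEFAULT_ENZYMES: tuple[MsreEnzyme, ...] = (
    MsreEnzyme("HpaII", "CCGG"),
    MsreEnzyme("HpyCH4IV", "ACGT"),
    MsreEnzyme("AciI", "CCGC"),
    MsreEnzyme("HinP1I", "GCGC"),
)


def _check_alphabet(seq: str) -> None:
    bad = set(seq) - _DNA
    if bad:
        raise ValueError(f"non-DNA characters in sequence: {sorted(bad)}")


def _find_all(seq: str, motif: str) -> list[int]:
    """All (possibly overlapping) occurrence positions of motif in seq."""
    hits = []
    start = seq.find(motif)
    while start != -1:
        hits.append(start)
        start = seq.find(motif, start + 1)
    return hits


def scan_recognition_sites(
    seq: str, enzymes: Sequence[MsreEnzyme] = DEFAULT_ENZYMES
) -> list[tuple[str, int, str]]:
    """Locate every MSRE recognition site on either strand.

    Forward-strand motif occurrences are reported with strand ``+``.
    Because a restriction enzyme cuts double-stranded DNA, occurrences of
    the reverse complement of a non-palindromic motif (CCGC -> GCGG) are
    also reported, at their forward-strand position, with strand ``-``.
    Palindromic motifs (CCGG, ACGT, GCGC) appear once.  ``N`` never matches.

    Returns ``(enzyme name, 0-based position, strand)`` sorted by position.
    """
    seq = seq.upper()
    _check_alphabet(seq)
    out: list[tuple[str, int, str]] = []
    for enz in enzymes:
        for pos in _find_all(seq, enz.motif):
            out.append((enz.name, pos, "+"))
        if not enz.is_palindromic:
            for pos in _find_all(seq, reverse_complement(enz.motif)):
                out.append((enz.name, pos, "-"))
    out.sort(key=lambda hit: (hit[1], hit[0], hit[2]))
    return out


def cpg_positions(seq: str) -> list[int]:
    """0-based positions of the C of every CG dinucleotide."""
    return _find_all(seq.upper(), "CG")


def cpg_coverage_fraction(seq: str, enzymes: Sequence[MsreEnzyme] = DEFAULT_ENZYMES) -> float:
    """Fraction of CpG dinucleotides covered by at least one recognition site.

    A CpG counts as covered when its dinucleotide (positions i, i+1)
    overlaps the 4-bp footprint of any recognition-site occurrence on
    either strand; overlap (rather than the C position alone) makes the
    fraction exactly invariant under reverse complementation.  Returns 0.0
    for a sequence without CpGs.
    """
    if not seq:
        raise ValueError("empty sequence")
    cpgs = cpg_positions(seq)
    if not cpgs:
        return 0.0
    covered_ranges = [(pos, pos + 4) for _, pos, _ in scan_recognition_sites(seq, enzymes)]
    n_cov = sum(1 for c in cpgs if any(lo < c + 2 and c < hi for lo, hi in covered_ranges))
    return n_cov / len(cpgs)


def classify_reference_region(seq: str, enzymes: Sequence[MsreEnzyme] = DEFAULT_ENZYMES) -> str:
    """Reference-region eligibility.

    A reference region must be immune to digestion: either it has no CpG at
    all (``ref_no_cpg``) or it has CpGs but no recognition site on either
    strand (``ref_no_site``).  Anything else is ``ineligible``.
    """
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    _check_alphabet(seq)
    if not cpg_positions(seq):
        return CATEGORY_REF_NO_CPG
    if not scan_recognition_sites(seq, enzymes):
        return CATEGORY_REF_NO_SITE
    return "ineligible"


def select_cpg_targets(
    betas: pd.DataFrame,
    groups: pd.DataFrame,
    site_info: Mapping[str, int],
    t_tumor: float = 0.5,
    t_normal: float = 0.3,
    mode: str = "per_type",
) -> list[str]:
    """Select hypermethylated candidate CpG sites from array beta values.

    A site is selected when (a) mean methylation in tumor samples is at
    least ``t_tumor`` (0.5), (b) mean methylation in normal tissue and in
    blood is at most ``t_normal`` (0.3), and (c) it carries at least one
    MSRE recognition site.

    Parameters
    ----------
    betas
        Sites x samples methylation levels in [0, 1].
    groups
        Indexed by sample id; columns ``condition`` (tumor/normal/blood)
        and ``tissue``.
    site_info
        Maps site id -> number of recognition sites in its region.
    mode
        ``per_type``: thresholds must hold within every tumor (resp.
        normal) tissue type separately.  ``pooled``: thresholds applied to
        the pooled tumor and pooled normal means.  Blood is always its own
        group.
    """
    if mode not in ("per_type", "pooled"):
        raise ValueError(f"unknown mode {mode!r}")
    missing_meta = set(betas.columns) - set(groups.index)
    if missing_meta:
        raise ValueError(f"samples without group labels: {sorted(missing_meta)}")
    missing_sites = set(betas.index) - set(site_info)
    if missing_sites:
        raise ValueError(f"sites without recognition-site info: {sorted(missing_sites)}")
    groups = groups.loc[betas.columns]
    if ((betas < 0) | (betas > 1)).any().any():
        raise ValueError("beta values must lie in [0, 1]")

    cond = groups["condition"]
    blood_cols = list(groups.index[cond == "blood"])
    if mode == "per_type":
        tumor_groups = [
            list(sub.index)
            for _, sub in groups[cond == "tumor"].groupby("tissue", sort=True)
        ]
        normal_groups = [
            list(sub.index)
            for _, sub in groups[cond == "normal"].groupby("tissue", sort=True)
        ]
    else:
        tumor_groups = [list(groups.index[cond == "tumor"])]
        normal_groups = [list(groups.index[cond == "normal"])]
    if blood_cols:
        normal_groups = normal_groups + [blood_cols]

    selected = []
    for site in betas.index:
        row = betas.loc[site]
        if site_info[site] < 1:
            continue
        if any(row[cols].mean() < t_tumor for cols in tumor_groups):
            continue
        if any(row[cols].mean() > t_normal for cols in normal_groups):
            continue
        selected.append(site)
    return selected


# ---------------------------------------------------------------------------
# Panel model


@dataclass(frozen=True)
class TargetRegion:
    """A captured region: 50-nt insert flanked by two ~20-nt arm landing sites."""

    id: str
    source: str  # "human-like" | "lambda"
    chrom: str
    start: int  # 0-based half-open, insert coordinates
    end: int
    category: str
    n_sites: int

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.end <= self.start:
            raise ValueError("end must exceed start")
        if self.category == CATEGORY_REF_NO_SITE and self.n_sites != 0:
            raise ValueError("ref_no_site region must have zero recognition sites")


@dataclass(frozen=True)
class Smmip:
    """One probe (tile) for a target; both arms plus capture geometry.

    ``lig_arm`` is the arm read first by read 1 (immediately after the
    5-nt UMI), ``ext_arm`` the arm at the far end of the captured molecule.
    """

    id: str
    target_id: str
    tile: str  # "plus" | "minus"
    ext_arm: str
    lig_arm: str
    backbone: str
    category: str
    umi_len_per_side: int = 5

    def __post_init__(self) -> None:
        if self.tile not in ("plus", "minus"):
            raise ValueError(f"tile must be plus/minus, got {self.tile!r}")
        if not self.ext_arm or not self.lig_arm:
            raise ValueError("arms must be non-empty")

    @property
    def umi_len_total(self) -> int:
        return 2 * self.umi_len_per_side


@dataclass
class Panel:
    """Targets, smMIPs and per-target reference (locus) sequences.

    ``sequences[target_id]`` is the plus-strand captured locus:
    lig-arm site (arm_len) + insert + ext-arm site (arm_len).  The molecule
    captured by a plus-tile smMIP is the locus itself; a minus tile captures
    its reverse complement.
    """

    targets: list[TargetRegion]
    smmips: list[Smmip]
    sequences: dict[str, str]
    enzymes: tuple[MsreEnzyme, ...] = DEFAULT_ENZYMES
    arm_len: int = 20

    def __post_init__(self) -> None:
        tids = {t.id for t in self.targets}
        for m in self.smmips:
            if m.target_id not in tids:
                raise ValueError(f"smMIP {m.id} references unknown target {m.target_id}")
        seen = set()
        for m in self.smmips:
            key = (m.target_id, m.tile)
            if key in seen:
                raise ValueError(f"duplicate tile {key}")
            seen.add(key)

    @property
    def target_by_id(self) -> dict[str, TargetRegion]:
        return {t.id: t for t in self.targets}

    @property
    def smmip_by_id(self) -> dict[str, Smmip]:
        return {m.id: m for m in self.smmips}

    def molecule_sequence(self, smmip: Smmip) -> str:
        locus = self.sequences[smmip.target_id]
        return locus if smmip.tile == "plus" else reverse_complement(locus)

    def smmip_meta(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "target_id": [m.target_id for m in self.smmips],
                "tile": [m.tile for m in self.smmips],
                "category": [m.category for m in self.smmips],
            },
            index=pd.Index([m.id for m in self.smmips], name="smmip_id"),
        )

    # -- I/O ---------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        tgt = self.target_by_id
        rows = []
        for m in self.smmips:
            t = tgt[m.target_id]
            rows.append(
                {
                    "id": m.id,
                    "target_id": m.target_id,
                    "tile": m.tile,
                    "chrom": t.chrom,
                    "start": t.start,
                    "end": t.end,
                    "category": m.category,
                    "ext_arm": m.ext_arm,
                    "lig_arm": m.lig_arm,
                    "n_sites": t.n_sites,
                }
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(self.sequences[t.id]), id=t.id, description=t.category)
            for t in self.targets
        ]
        SeqIO.write(records, str(path), "fasta")

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for t in self.targets:
                fh.write(f"{t.chrom}\t{t.start}\t{t.end}\t{t.id}\n")

    @classmethod
    def from_files(cls, tsv_path: str | Path, fasta_path: str | Path, backbone: str = "") -> "Panel":
        df = pd.read_csv(tsv_path, sep="\t")
        sequences = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
        targets: dict[str, TargetRegion] = {}
        smmips = []
        for _, row in df.iterrows():
            tid = row["target_id"]
            if tid not in targets:
                targets[tid] = TargetRegion(
                    id=tid,
                    source="lambda" if str(row["category"]).startswith("lambda") else "human-like",
                    chrom=row["chrom"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    category=row["category"],
                    n_sites=int(row["n_sites"]),
                )
            smmips.append(
                Smmip(
                    id=row["id"],
                    target_id=tid,
                    tile=row["tile"],
                    ext_arm=row["ext_arm"],
                    lig_arm=row["lig_arm"],
                    backbone=backbone,
                    category=row["category"],
                )
            )
        return cls(targets=list(targets.values()), smmips=smmips, sequences=sequences)
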