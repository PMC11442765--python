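"""FASTQ to deduplicated per-smMIP counts.

Stages: demultiplex on the two sample-barcode index reads (one mismatch
allowed per barcode), assign each read pair to a panel smMIP by looking up
its arm sequences (exact, with a one-mismatch fallback) within a small
positional window, filter on a pairing-quality score, collapse PCR
duplicates on the combined 10-nt UMI and count unique molecules.

The assay targets known loci, so assignment is done against the panel
reference by arm lookup rather than whole-genome alignment; a pair is
retained only when both mates match the same target within a 5-bp offset
margin of the expected smMIP location.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .matrix import CountMatrix
from .panel import Panel, reverse_complement
from .simulate import ReadSet, hamming

#: mapping-quality proxy: perfect arm matches score 60, each arm mismatch
#: costs 20 (so one mismatched arm still passes the >15 filter).
_Q_PERFECT = 60
_Q_PER_MISMATCH = 20


@dataclass
class ReadPairRecord:
    name: str
    sample_id: str | None
    smmip_id: str | None
    umi: str | None
    offsets: tuple[int, int] | None
    quality: int
    reason: str | None  # discard reason when not countable


def validate_barcode_table(table: pd.DataFrame) -> None:
    """Require every sample pair to be >= 3 combined mismatches apart."""
    ids = list(table.index)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            d = hamming(table.loc[a, "barcode1"], table.loc[b, "barcode1"]) + hamming(
                table.loc[a, "barcode2"], table.loc[b, "barcode2"]
            )
            if d < 3:
                raise ValueError(
                    f"barcode pairs for {a} and {b} are only {d} mismatches apart (<3): "
                    "demultiplexing would be ambiguous"
                )


def demultiplex(
    i1: str, i2: str, barcode_table: pd.DataFrame, max_mismatch: int = 1
) -> str | None:
    """Assign a read pair to a sample from its two index reads.

    Assigned iff each barcode matches the sample's barcode within
    ``max_mismatch`` (default 1) and exactly one sample matches; ambiguous
    or distant reads are unassigned (None).
    """
    hits = [
        sid
        for sid, row in barcode_table.iterrows()
        if hamming(i1, row["barcode1"]) <= max_mismatch
        and hamming(i2, row["barcode2"]) <= max_mismatch
    ]
    return hits[0] if len(hits) == 1 else None


class ArmIndex:
    """Per-mate lookup of arm keys to smMIP ids.

    Key 1 is the first ``arm_len`` bases of the captured molecule (read-1
    proximal arm); key 2 the first ``arm_len`` bases of its reverse
    complement (read-2 proximal).  Exact dictionary lookup first, then a
    one-mismatch linear fallback.
    """

    def __init__(self, panel: Panel):
        self.arm_len = panel.arm_len
        self.key1: dict[str, str] = {}
        self.key2: dict[str, str] = {}
        for smmip in panel.smmips:
            mol = panel.molecule_sequence(smmip)
            k1 = mol[: self.arm_len]
            k2 = reverse_complement(mol)[: self.arm_len]
            if k1 in self.key1 or k2 in self.key2:
                raise ValueError(f"arm key collision for smMIP {smmip.id}")
            self.key1[k1] = smmip.id
            self.key2[k2] = smmip.id

    def _lookup(self, table: dict[str, str], seq: str, max_shift: int) -> tuple[str, int, int] | None:
        """Return (smmip id, offset, mismatches) for the best arm hit."""
        L = self.arm_len
        for shift in range(0, max_shift + 1):
            window = seq[shift : shift + L]
            if len(window) < L:
                break
            hit = table.get(window)
            if hit is not None:
                return hit, shift, 0
        best = None
        for shift in range(0, max_shift + 1):
            window = seq[shift : shift + L]
            if len(window) < L:
                break
            for key, sid in table.items():
                if hamming(window, key) <= 1:
                    if best is None:
                        best = (sid, shift, 1)
        return best

    def lookup1(self, seq: str, max_shift: int = 8):
        return self._lookup(self.key1, seq, max_shift)

    def lookup2(self, seq: str, max_shift: int = 8):
        return self._lookup(self.key2, seq, max_shift)


def assign_read_pair(
    r1_trimmed: str,
    r2_trimmed: str,
    index: ArmIndex,
    margin: int = 5,
) -> tuple[str | None, tuple[int, int], int, str | None]:
    """Assign a UMI-trimmed read pair to a smMIP.

    Both mates must hit the same smMIP and each mate's start-coordinate
    offset from the expected location must be at most ``margin`` (inclusive)
    base pairs.  Returns (smmip id or None, offsets, quality, reason).
    """
    hit1 = index.lookup1(r1_trimmed, max_shift=margin + 3)
    hit2 = index.lookup2(r2_trimmed, max_shift=margin + 3)
    if hit1 is None or hit2 is None:
        return None, (0, 0), 0, "unmatched_arm"
    sid1, off1, mm1 = hit1
    sid2, off2, mm2 = hit2
    quality = _Q_PERFECT - _Q_PER_MISMATCH * (mm1 + mm2)
    if sid1 != sid2:
        return None, (off1, off2), quality, "mate_target_mismatch"
    if abs(off1) > margin or abs(off2) > margin:
        return None, (off1, off2), quality, "offset_exceeded"
    return sid1, (off1, off2), quality, None


def quality_filter(quality: int, properly_paired: bool, min_quality: int = 15) -> bool:
    """Keep only properly paired reads with quality strictly above the cutoff."""
    return properly_paired and quality > min_quality


def deduplicate(records: Iterable[ReadPairRecord]) -> tuple[list[ReadPairRecord], int]:
    """One representative per (sample, smMIP, UMI); first in input order wins.

    Returns (unique records, number of duplicates removed).  Records whose
    UMI contains N are discarded upstream.
    """
    seen: set[tuple[str, str, str]] = set()
    unique: list[ReadPairRecord] = []
    dups = 0
    for rec in records:
        key = (rec.sample_id, rec.smmip_id, rec.umi)
        if key in seen:
            dups += 1
            continue
        seen.add(key)
        unique.append(rec)
    return unique, dups


def count(
    unique_records: Iterable[ReadPairRecord],
    sample_meta: pd.DataFrame,
    panel: Panel,
) -> CountMatrix:
    """Tally unique molecules into a samples x smMIPs matrix (zeros kept)."""
    smmip_ids = [p.id for p in panel.smmips]
    counts = pd.DataFrame(0, index=sample_meta.index, columns=smmip_ids, dtype=np.int64)
    tally = Counter((rec.sample_id, rec.smmip_id) for rec in unique_records)
    for (sid, pid), n in tally.items():
        counts.loc[sid, pid] = n
    return CountMatrix(counts=counts, sample_meta=sample_meta, smmip_meta=panel.smmip_meta())


@dataclass
class ProcessResult:
    counts: CountMatrix
    discard_tally: dict[str, int]
    n_read_pairs: int
    n_counted: int

    def tally_frame(self) -> pd.DataFrame:
        rows = dict(self.discard_tally)
        rows["counted_unique"] = self.n_counted
        rows["total_read_pairs"] = self.n_read_pairs
        return pd.DataFrame(
            {"reads": pd.Series(rows, dtype=np.int64)}
        ).rename_axis("stage")


def process_reads(
    reads: ReadSet,
    panel: Panel,
    barcode_table: pd.DataFrame,
    sample_meta: pd.DataFrame,
    umi_len_per_side: int = 5,
    min_quality: int = 15,
    margin: int = 5,
) -> ProcessResult:
    """Full read-level pipeline: demux, assign, filter, dedup, count.

    ``discard_tally`` accounts for every read pair not counted, by reason;
    discarded + duplicates + counted always equals the number of pairs.
    """
    validate_barcode_table(barcode_table)
    index = ArmIndex(panel)
    ulen = umi_len_per_side
    tally: Counter[str] = Counter()
    kept: list[ReadPairRecord] = []
    # exact-barcode fast path; mismatched barcodes fall back to the scan
    exact = {
        (row["barcode1"], row["barcode2"]): sid for sid, row in barcode_table.iterrows()
    }
    for name, r1, r2, i1, i2 in zip(reads.names, reads.r1, reads.r2, reads.i1, reads.i2):
        sample_id = exact.get((i1, i2))
        if sample_id is None:
            sample_id = demultiplex(i1, i2, barcode_table)
        if sample_id is None:
            tally["unassigned_sample"] += 1
            continue
        umi = r1[:ulen] + r2[:ulen]
        if "N" in umi:
            tally["umi_contains_n"] += 1
            continue
        smmip_id, offsets, quality, reason = assign_read_pair(
            r1[ulen:], r2[ulen:], index, margin=margin
        )
        if smmip_id is None:
            tally[reason] += 1
            continue
        if not quality_filter(quality, properly_paired=True, min_quality=min_quality):
            tally["low_quality"] += 1
            continue
        kept.append(
            ReadPairRecord(
                name=name,
                sample_id=sample_id,
                smmip_id=smmip_id,
                umi=umi,
                offsets=offsets,
                quality=quality,
                reason=None,
            )
        )
    unique, dups = deduplicate(kept)
    tally["pcr_duplicate"] = dups
    cm = count(unique, sample_meta, panel)
    return ProcessResult(
        counts=cm,
        discard_tally=dict(tally),
        n_read_pairs=len(reads),
        n_counted=len(unique),
    )
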