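"""Synthetic assay simulator.

Emulates the full molecular process at two levels:

* count level (:func:`simulate_counts`) — per sample and target, molecules
  survive MSRE digestion with probability ``m + (1 - m) * eps_nd`` (fraction
  methylated plus incomplete digestion of the unmethylated fraction), are
  captured with a fixed efficiency, and the resulting deduplicated count is
  binomial.  Reference targets (no recognition site / no CpG) always
  survive; unmethylated lambda spike-in CpG targets survive only through
  incomplete digestion; undigested control samples skip digestion entirely.
* read level (:func:`simulate_reads`) — every surviving captured molecule
  is expanded into one or more PCR-duplicate read pairs sharing a single
  10-nt UMI (5 nt per mate), with dual sample-barcode index reads and
  optional uniform substitution errors.

Per-sample, per-target methylation truth is drawn from condition-specific
Beta distributions (tumor high, adjacent normal low, blood lowest) and
returned as a :class:`TruthTable` so downstream estimates can be checked
against ground truth.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .matrix import (
    CATEGORY_CPG,
    CATEGORY_LAMBDA_CPG,
    CATEGORY_LAMBDA_REF,
    CATEGORY_REF_NO_CPG,
    CATEGORY_REF_NO_SITE,
    CountMatrix,
)
from .panel import (
    DEFAULT_ENZYMES,
    Panel,
    Smmip,
    TargetRegion,
    cpg_positions,
    reverse_complement,
    scan_recognition_sites,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")

#: Default per-condition Beta(a, b) parameters for per-sample target
#: methylation.  Means: tumor 0.55, adjacent normal 0.25, blood 0.15 —
#: hypermethylated panel targets separate tumor from normal, blood lowest.
DEFAULT_METHYLATION_BETAS: dict[str, tuple[float, float]] = {
    "tumor": (5.5, 4.5),
    "normal": (2.5, 7.5),
    "blood": (1.5, 8.5),
}

_BACKBONE = "CTTCAGCTTCCCGATATCCGACGGTAGTGT"  # constant 30-nt smMIP backbone


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("length mismatch")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class SampleSpec:
    id: str
    tissue: str
    condition: str  # tumor | normal | blood
    digested: bool
    barcode1: str
    barcode2: str


@dataclass
class SimConfig:
    """All knobs of the simulator; every random choice derives from ``seed``."""

    seed: int
    samples: list[SampleSpec]
    n_molecules_per_target: int = 1000
    capture_efficiency: float = 0.5
    non_digestion_rate: float = 0.013
    pcr_duplication_mean: float = 1.0
    read_error_rate: float = 0.0
    methylation_betas: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_METHYLATION_BETAS)
    )
    umi_len_per_side: int = 5
    read_len: int = 50

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("capture_efficiency", "non_digestion_rate", "read_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.pcr_duplication_mean < 1.0:
            raise ValueError("pcr_duplication_mean must be >= 1")
        if self.n_molecules_per_target < 0:
            raise ValueError("n_molecules_per_target must be >= 0")
        ids = [s.id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids")
        for s in self.samples:
            if s.condition not in ("tumor", "normal", "blood"):
                raise ValueError(f"{s.id}: unknown condition {s.condition!r}")
        for i, a in enumerate(self.samples):
            for b in self.samples[i + 1 :]:
                d = hamming(a.barcode1, b.barcode1) + hamming(a.barcode2, b.barcode2)
                if d < 3:
                    raise ValueError(
                        f"barcode collision between {a.id} and {b.id}: "
                        f"combined distance {d} < 3"
                    )

    def sample_meta(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tissue": [s.tissue for s in self.samples],
                "condition": [s.condition for s in self.samples],
                "digested": [s.digested for s in self.samples],
            },
            index=pd.Index([s.id for s in self.samples], name="sample_id"),
        )

    def barcode_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "barcode1": [s.barcode1 for s in self.samples],
                "barcode2": [s.barcode2 for s in self.samples],
            },
            index=pd.Index([s.id for s in self.samples], name="sample_id"),
        )


@dataclass
class TruthTable:
    """Ground truth of a simulation.

    ``methylation[sample, target]`` is the true methylated fraction m
    (NaN for reference targets, where digestion plays no role);
    ``spike_fraction[sample]`` is the true spike-in fraction for mixture
    experiments (NaN otherwise).
    """

    methylation: pd.DataFrame
    spike_fraction: pd.Series

    def to_tsv(self, path: str | Path) -> None:
        df = self.methylation.copy()
        df.insert(0, "spike_fraction", self.spike_fraction)
        df.rename_axis("sample_id").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Synthetic panel construction


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _random_clean_seq(rng: np.random.Generator, n: int, forbid_cpg: bool = True) -> str:
    """Random sequence without recognition sites (and optionally no CpG)."""
    for _ in range(10_000):
        s = _random_seq(rng, n)
        if forbid_cpg and "CG" in s:
            continue
        if scan_recognition_sites(s):
            continue
        return s
    raise RuntimeError("failed to generate clean sequence")  # pragma: no cover


def _cpg_insert(rng: np.random.Generator, length: int, n_sites: int) -> str:
    """Insert carrying ``n_sites`` recognition-site occurrences."""
    for _ in range(10_000):
        base = list(_random_clean_seq(rng, length, forbid_cpg=True))
        starts = rng.choice((length - 4) // 5, size=n_sites, replace=False) * 5
        for p in starts:
            motif = DEFAULT_ENZYMES[rng.integers(len(DEFAULT_ENZYMES))].motif
            base[p : p + 4] = motif
        seq = "".join(base)
        if len(scan_recognition_sites(seq)) == n_sites:
            return seq
    raise RuntimeError("failed to embed recognition sites")  # pragma: no cover


def make_panel(
    seed: int,
    n_cpg_targets: int = 30,
    n_double_tiled: int = 10,
    n_ref_no_site: int = 10,
    n_ref_no_cpg: int = 10,
    n_lambda_cpg: int = 4,
    n_lambda_ref: int = 4,
    insert_len: int = 50,
    arm_len: int = 20,
) -> Panel:
    """Generate a synthetic panel with unique smMIP arms.

    CpG targets carry 2-6 recognition sites (mean ~4 per region); reference
    targets carry none (half additionally carry no CpG); lambda targets
    mirror both flavors on the unmethylated phage spike-in.
    """
    rng = np.random.default_rng(seed)
    targets: list[TargetRegion] = []
    smmips: list[Smmip] = []
    sequences: dict[str, str] = {}
    used_keys: set[str] = set()

    def add_target(tid, source, chrom, idx, category, insert):
        # assemble locus, rejecting junction-made sites for clean categories
        for _ in range(1000):
            left = _random_clean_seq(rng, arm_len, forbid_cpg=True)
            right = _random_clean_seq(rng, arm_len, forbid_cpg=True)
            locus = left + insert + right
            n_locus_sites = len(scan_recognition_sites(locus))
            n_insert_sites = len(scan_recognition_sites(insert))
            if category in (CATEGORY_REF_NO_SITE, CATEGORY_REF_NO_CPG, CATEGORY_LAMBDA_REF):
                if n_locus_sites != 0:
                    continue
                if category == CATEGORY_REF_NO_CPG and "CG" in locus:
                    continue
            elif n_locus_sites != n_insert_sites:
                continue
            keys = {locus[:arm_len], reverse_complement(locus[-arm_len:])}
            if keys & used_keys or len(keys) < 2:
                continue
            used_keys.update(keys)
            break
        else:  # pragma: no cover
            raise RuntimeError("failed to assemble locus")
        start = idx * (insert_len + 2 * arm_len + 10)
        targets.append(
            TargetRegion(
                id=tid,
                source=source,
                chrom=chrom,
                start=start,
                end=start + insert_len,
                category=category,
                n_sites=n_insert_sites,
            )
        )
        sequences[tid] = locus
        return locus

    def add_smmip(tid, tile, category):
        locus = sequences[tid]
        if tile == "plus":
            lig, ext = locus[:arm_len], locus[-arm_len:]
        else:
            rc = reverse_complement(locus)
            lig, ext = rc[:arm_len], rc[-arm_len:]
        smmips.append(
            Smmip(
                id=f"{tid}_{'p' if tile == 'plus' else 'm'}",
                target_id=tid,
                tile=tile,
                ext_arm=ext,
                lig_arm=lig,
                backbone=_BACKBONE,
                category=category,
            )
        )

    idx = 0
    for i in range(n_cpg_targets):
        tid = f"cpg{i:04d}"
        n_sites = int(rng.integers(2, 7))
        add_target(tid, "human-like", "panel1", idx, CATEGORY_CPG, _cpg_insert(rng, insert_len, n_sites))
        add_smmip(tid, "plus", CATEGORY_CPG)
        if i < n_double_tiled:
            add_smmip(tid, "minus", CATEGORY_CPG)
        idx += 1
    for i in range(n_ref_no_site):
        tid = f"refs{i:04d}"
        # no recognition site but CpGs allowed: inject a CG if absent
        for _ in range(1000):
            ins = _random_clean_seq(rng, insert_len, forbid_cpg=False)
            if "CG" in ins and not scan_recognition_sites(ins):
                break
        add_target(tid, "human-like", "panel1", idx, CATEGORY_REF_NO_SITE, ins)
        add_smmip(tid, "plus", CATEGORY_REF_NO_SITE)
        idx += 1
    for i in range(n_ref_no_cpg):
        tid = f"refc{i:04d}"
        add_target(tid, "human-like", "panel1", idx, CATEGORY_REF_NO_CPG, _random_clean_seq(rng, insert_len))
        add_smmip(tid, "plus", CATEGORY_REF_NO_CPG)
        idx += 1
    for i in range(n_lambda_cpg):
        tid = f"lcpg{i:02d}"
        n_sites = int(rng.integers(1, 4))
        add_target(tid, "lambda", "lambda", idx, CATEGORY_LAMBDA_CPG, _cpg_insert(rng, insert_len, n_sites))
        add_smmip(tid, "plus", CATEGORY_LAMBDA_CPG)
        idx += 1
    for i in range(n_lambda_ref):
        tid = f"lref{i:02d}"
        add_target(tid, "lambda", "lambda", idx, CATEGORY_LAMBDA_REF, _random_clean_seq(rng, insert_len))
        add_smmip(tid, "plus", CATEGORY_LAMBDA_REF)
        idx += 1

    return Panel(targets=targets, smmips=smmips, sequences=sequences, arm_len=arm_len)


# ---------------------------------------------------------------------------
# Sample sheets and barcodes


def make_barcodes(n: int, rng: np.random.Generator, length: int = 8) -> list[tuple[str, str]]:
    """Dual barcode pairs with pairwise combined Hamming distance >= 3."""
    pairs: list[tuple[str, str]] = []
    for _ in range(100_000):
        if len(pairs) == n:
            return pairs
        cand = (_random_seq(rng, length), _random_seq(rng, length))
        ok = all(
            hamming(cand[0], p[0]) + hamming(cand[1], p[1]) >= 3 for p in pairs
        )
        if ok:
            pairs.append(cand)
    raise RuntimeError("failed to generate barcode set")  # pragma: no cover


def default_sample_sheet(
    seed: int,
    n_tumor: int = 5,
    n_normal: int = 3,
    n_blood: int = 2,
    n_undigested: int = 2,
    tissues: Sequence[str] = ("lung", "colorectal", "liver", "breast", "pancreas"),
    barcode_len: int = 8,
) -> list[SampleSpec]:
    """Study-like sample sheet: tumor/normal tissue, blood, undigested controls."""
    rng = np.random.default_rng([seed, 20011])
    total = n_tumor + n_normal + n_blood + n_undigested
    barcodes = make_barcodes(total, rng, barcode_len)
    samples = []
    k = 0
    for i in range(n_tumor):
        samples.append(SampleSpec(f"T{i:03d}", tissues[i % len(tissues)], "tumor", True, *barcodes[k]))
        k += 1
    for i in range(n_normal):
        samples.append(SampleSpec(f"N{i:03d}", tissues[i % len(tissues)], "normal", True, *barcodes[k]))
        k += 1
    for i in range(n_blood):
        samples.append(SampleSpec(f"B{i:03d}", "blood", "blood", True, *barcodes[k]))
        k += 1
    for i in range(n_undigested):
        samples.append(SampleSpec(f"U{i:03d}", "control", "normal", False, *barcodes[k]))
        k += 1
    return samples


# ---------------------------------------------------------------------------
# Count-level simulation


def _survival_probability(category: str, m: float, digested: bool, eps_nd: float) -> float:
    if not digested:
        return 1.0
    if category in (CATEGORY_REF_NO_SITE, CATEGORY_REF_NO_CPG, CATEGORY_LAMBDA_REF):
        return 1.0
    if category == CATEGORY_LAMBDA_CPG:
        return eps_nd  # lambda DNA is never methylated
    return m + (1.0 - m) * eps_nd


def _draw_methylation(panel: Panel, config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    tids = [t.id for t in panel.targets]
    cats = {t.id: t.category for t in panel.targets}
    m = pd.DataFrame(np.nan, index=[s.id for s in config.samples], columns=tids)
    cpg_tids = [t for t in tids if cats[t] == CATEGORY_CPG]
    for s in config.samples:
        a, b = config.methylation_betas[s.condition]
        m.loc[s.id, cpg_tids] = rng.beta(a, b, size=len(cpg_tids))
        m.loc[s.id, [t for t in tids if cats[t] == CATEGORY_LAMBDA_CPG]] = 0.0
    m.index.name = "sample_id"
    return m


def _counts_from_m(
    panel: Panel,
    config: SimConfig,
    m: pd.DataFrame,
    rng: np.random.Generator,
    sample_meta: pd.DataFrame,
) -> CountMatrix:
    smmip_ids = [p.id for p in panel.smmips]
    eps = config.non_digestion_rate
    rows = np.empty((len(sample_meta), len(smmip_ids)), dtype=np.int64)
    for i, sid in enumerate(sample_meta.index):
        digested = bool(sample_meta.loc[sid, "digested"])
        probs = np.empty(len(smmip_ids))
        for j, smmip in enumerate(panel.smmips):
            mv = m.loc[sid, smmip.target_id]
            surv = _survival_probability(smmip.category, 0.0 if np.isnan(mv) else mv, digested, eps)
            probs[j] = config.capture_efficiency * surv
        rows[i] = rng.binomial(config.n_molecules_per_target, probs)
    counts = pd.DataFrame(rows, index=sample_meta.index, columns=smmip_ids)
    return CountMatrix(counts=counts, sample_meta=sample_meta, smmip_meta=panel.smmip_meta())


def simulate_counts(panel: Panel, config: SimConfig) -> tuple[CountMatrix, TruthTable]:
    """Deduplicated count matrix drawn directly at the molecule level.

    For a digested sample the expected count of a CpG smMIP is
    ``n_molecules * capture_efficiency * (m + (1 - m) * eps_nd)``; reference
    smMIPs always survive, lambda CpG smMIPs survive only through
    incomplete digestion, and undigested samples skip digestion.
    """
    if not any(p.category == CATEGORY_LAMBDA_CPG for p in panel.smmips) or not any(
        p.category == CATEGORY_LAMBDA_REF for p in panel.smmips
    ):
        raise ValueError("panel must contain lambda CpG and lambda reference smMIPs")
    rng = np.random.default_rng(config.seed)
    m = _draw_methylation(panel, config, rng)
    cm = _counts_from_m(panel, config, m, rng, config.sample_meta())
    truth = TruthTable(
        methylation=m,
        spike_fraction=pd.Series(np.nan, index=m.index, name="spike_fraction"),
    )
    return cm, truth


def simulate_spikein_series(
    panel: Panel,
    config: SimConfig,
    fractions: Sequence[float],
    replicates: int = 3,
) -> tuple[CountMatrix, TruthTable]:
    """Mixture series: tumor DNA spiked into an unmethylated background.

    One tumor methylation profile and one background (blood-like) profile
    are drawn per target; a sample at spike fraction ``f`` has per-target
    ``m = f * m_tumor + (1 - f) * m_background``.  ``replicates`` digested
    samples are simulated per fraction, reusing the barcodes of
    ``config.samples`` (which must be large enough), plus the undigested
    controls present in the config.
    """
    if any(not 0.0 <= f <= 1.0 for f in fractions):
        raise ValueError("fractions must lie in [0, 1]")
    rng = np.random.default_rng([config.seed, 104729])
    tids = [t.id for t in panel.targets]
    cats = {t.id: t.category for t in panel.targets}
    cpg_tids = [t for t in tids if cats[t] == CATEGORY_CPG]
    a_t, b_t = config.methylation_betas["tumor"]
    a_b, b_b = config.methylation_betas["blood"]
    m_tumor = pd.Series(rng.beta(a_t, b_t, size=len(cpg_tids)), index=cpg_tids)
    m_bg = pd.Series(rng.beta(a_b, b_b, size=len(cpg_tids)), index=cpg_tids)

    rows = []
    meta_rows = []
    spike = {}
    for f in fractions:
        for j in range(replicates):
            sid = f"spike{int(round(100 * f)):03d}r{j}"
            mrow = pd.Series(np.nan, index=tids, name=sid)
            mrow[cpg_tids] = f * m_tumor + (1.0 - f) * m_bg
            mrow[[t for t in tids if cats[t] == CATEGORY_LAMBDA_CPG]] = 0.0
            rows.append(mrow)
            meta_rows.append({"sample_id": sid, "tissue": "mixture", "condition": "tumor", "digested": True})
            spike[sid] = f
    for s in config.samples:
        if not s.digested:
            mrow = pd.Series(np.nan, index=tids, name=s.id)
            mrow[cpg_tids] = m_bg
            mrow[[t for t in tids if cats[t] == CATEGORY_LAMBDA_CPG]] = 0.0
            rows.append(mrow)
            meta_rows.append({"sample_id": s.id, "tissue": s.tissue, "condition": s.condition, "digested": False})
            spike[s.id] = np.nan

    m = pd.DataFrame(rows)
    m.index.name = "sample_id"
    sample_meta = pd.DataFrame(meta_rows).set_index("sample_id")
    cm = _counts_from_m(panel, config, m, rng, sample_meta)
    truth = TruthTable(methylation=m, spike_fraction=pd.Series(spike, name="spike_fraction"))
    return cm, truth


# ---------------------------------------------------------------------------
# Read-level simulation


@dataclass
class ReadSet:
    """Paired reads plus the two index (barcode) reads, parallel lists."""

    names: list[str]
    r1: list[str]
    r2: list[str]
    i1: list[str]
    i2: list[str]

    def __len__(self) -> int:
        return len(self.names)

    def write(self, out_dir: str | Path, gz: bool = True) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        suffix = ".fastq.gz" if gz else ".fastq"
        for label, seqs in (("R1", self.r1), ("R2", self.r2), ("I1", self.i1), ("I2", self.i2)):
            path = out_dir / f"{label}{suffix}"
            opener = gzip.open if gz else open
            with opener(path, "wt") as fh:
                fh.writelines(
                    f"@{n}\n{s}\n+\n{'I' * len(s)}\n" for n, s in zip(self.names, seqs)
                )
            paths[label] = path
        return paths

    @classmethod
    def read(cls, r1, r2, i1, i2) -> "ReadSet":
        def load(path):
            path = str(path)
            opener = gzip.open if path.endswith(".gz") else open
            with opener(path, "rt") as fh:
                return [(title.split()[0], seq) for title, seq, _ in FastqGeneralIterator(fh)]

        a, b, c, d = load(r1), load(r2), load(i1), load(i2)
        return cls(
            names=[n for n, _ in a],
            r1=[s for _, s in a],
            r2=[s for _, s in b],
            i1=[s for _, s in c],
            i2=[s for _, s in d],
        )


def _unique_umis(rng: np.random.Generator, n: int, length: int) -> list[str]:
    """n distinct UMI strings; resample collisions so dedup is lossless."""
    umis: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        need = n - len(out)
        block = rng.integers(0, 4, size=(need, length))
        for row in block:
            u = "".join(_BASES[row])
            if u not in umis:
                umis.add(u)
                out.append(u)
    return out


def _mutate(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0.0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(len(arr)) < rate
    if hit.any():
        idx = np.nonzero(hit)[0]
        subs = rng.integers(1, 4, size=len(idx))
        lut = {b"A": "ACGT", b"C": "CGTA", b"G": "GTAC", b"T": "TACG"}
        for i, s in zip(idx, subs):
            arr[i] = lut.get(arr[i].tobytes(), "ACGT")[s % 4].encode()
    return arr.tobytes().decode()


def simulate_reads(
    panel: Panel, config: SimConfig
) -> tuple[ReadSet, CountMatrix, TruthTable]:
    """Expand :func:`simulate_counts` molecules into PCR-duplicated read pairs.

    Read 1 is a 5-nt UMI followed by the molecule 5' end (lig arm + insert
    prefix); read 2 is a 5-nt UMI followed by the reverse complement of the
    molecule 3' end.  Each molecule yields a geometric number of read pairs
    (mean ``pcr_duplication_mean``, minimum 1) sharing the same UMI pair;
    UMIs are distinct between molecules of the same sample and smMIP, so a
    zero-error run deduplicates exactly back to the simulated counts.
    """
    counts, truth = simulate_counts(panel, config)
    rng = np.random.default_rng([config.seed, 7919])
    payload = config.read_len - config.umi_len_per_side
    ulen = config.umi_len_per_side
    p_geom = 1.0 / config.pcr_duplication_mean

    names: list[str] = []
    r1s: list[str] = []
    r2s: list[str] = []
    i1s: list[str] = []
    i2s: list[str] = []
    serial = 0
    for spec in config.samples:
        for smmip in panel.smmips:
            c = int(counts.counts.loc[spec.id, smmip.id])
            if c == 0:
                continue
            molecule = panel.molecule_sequence(smmip)
            fwd = molecule[:payload]
            rev = reverse_complement(molecule)[:payload]
            umis = _unique_umis(rng, c, 2 * ulen)
            ndups = rng.geometric(p_geom, size=c)
            for u, nd in zip(umis, ndups):
                u1, u2 = u[:ulen], u[ulen:]
                for _ in range(int(nd)):
                    names.append(f"rp{serial:08d}")
                    serial += 1
                    r1s.append(_mutate(u1 + fwd, rng, config.read_error_rate))
                    r2s.append(_mutate(u2 + rev, rng, config.read_error_rate))
                    i1s.append(_mutate(spec.barcode1, rng, config.read_error_rate))
                    i2s.append(_mutate(spec.barcode2, rng, config.read_error_rate))
    order = rng.permutation(len(names))
    reads = ReadSet(
        names=[names[i] for i in order],
        r1=[r1s[i] for i in order],
        r2=[r2s[i] for i in order],
        i1=[i1s[i] for i in order],
        i2=[i2s[i] for i in order],
    )
    return reads, counts, truth
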