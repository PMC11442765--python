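"""Normalization and the ensemble LDA tumor/normal classifier.

The classifier construction mirrors the assay's analysis: counts are
normalized per sample by the summed reference smMIP counts; every CpG smMIP
gets its own one-dimensional linear discriminant (equal-variance Gaussian)
model scored by stratified 5-fold cross-validated AUC; smMIPs below a
cvAUC of 0.8 or below 1000 cumulative counts in the undigested samples are
removed; of double-tiled smMIPs only the better tile is kept; each
remaining single-smMIP model receives the score cutoff minimizing
FP + FN; and the ensemble calls "tumor" when at least ``k`` single models
agree, ``k`` chosen to maximize training accuracy.

`ReferenceNormalizer` and `EnsembleLdaClassifier` follow the scikit-learn
estimator protocol (``fit`` / ``transform`` / ``predict``, fitted
attributes with trailing underscores); the module-level functions are the
individual steps and remain usable on their own.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin

from .matrix import CountMatrix


# ---------------------------------------------------------------------------
# Normalization


@dataclass
class NormalizedMatrix:
    """Per-sample reference-normalized counts plus the reference set used."""

    values: pd.DataFrame
    reference_ids: list[str]


def normalize(counts: CountMatrix, reference_ids: Sequence[str] | None = None) -> NormalizedMatrix:
    """Divide every count by the sample's summed reference smMIP counts."""
    refs = list(reference_ids) if reference_ids is not None else counts.reference_ids
    if not refs:
        raise ValueError("no reference smMIPs available for normalization")
    ref_sums = counts.counts[refs].sum(axis=1)
    zero = ref_sums.index[ref_sums == 0]
    if len(zero):
        raise ValueError(f"zero reference counts in samples: {list(zero)}")
    return NormalizedMatrix(values=counts.counts.div(ref_sums, axis=0), reference_ids=refs)


class ReferenceNormalizer(TransformerMixin, BaseEstimator):
    """sklearn transformer wrapping reference-count normalization.

    Parameters
    ----------
    reference_ids : list of column names to sum as the per-sample
        normalization denominator.
    """

    def __init__(self, reference_ids: Sequence[str] | None = None):
        self.reference_ids = reference_ids

    def fit(self, X: pd.DataFrame, y=None):
        if self.reference_ids is None:
            raise ValueError("reference_ids must be provided")
        missing = set(self.reference_ids) - set(X.columns)
        if missing:
            raise ValueError(f"reference columns missing from input: {sorted(missing)}")
        self.reference_ids_ = list(self.reference_ids)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        ref_sums = X[self.reference_ids_].sum(axis=1)
        zero = ref_sums.index[ref_sums == 0]
        if len(zero):
            raise ValueError(f"zero reference counts in samples: {list(zero)}")
        return X.div(ref_sums, axis=0)


# ---------------------------------------------------------------------------
# Cross-validation folds


def stratified_folds(strata: Sequence, n_folds: int = 5, seed: int = 0) -> np.ndarray:
    """Random fold assignment stratified on the given labels.

    Members of each stratum (here: tissue x condition) are shuffled and
    dealt cyclically so per-stratum fold sizes differ by at most one.
    Deterministic for a given seed.
    """
    strata = np.asarray(strata)
    if len(strata) < n_folds:
        raise ValueError(f"{len(strata)} samples cannot fill {n_folds} folds")
    rng = np.random.default_rng(seed)
    folds = np.empty(len(strata), dtype=np.int64)
    for label in sorted(pd.unique(strata), key=str):
        idx = np.flatnonzero(strata == label)
        if len(idx) < n_folds:
            warnings.warn(
                f"stratum {label!r} has {len(idx)} samples for {n_folds} folds; "
                "some folds will not contain it",
                stacklevel=2,
            )
        perm = rng.permutation(idx)
        start = int(rng.integers(n_folds))
        for j, i in enumerate(perm):
            folds[i] = (start + j) % n_folds
    return folds


# ---------------------------------------------------------------------------
# Single-smMIP LDA


@dataclass
class LdaModel1D:
    """Equal-variance Gaussian discriminant on one normalized-count feature.

    ``score`` is the signed log-ratio of class discriminants, oriented so
    larger values favor the tumor class.  ``var`` is the pooled
    within-class variance with an (n - 2) denominator.
    """

    mu_tumor: float
    mu_normal: float
    var: float
    prior_tumor: float
    prior_normal: float

    @property
    def degenerate(self) -> bool:
        return self.var == 0.0

    def score(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if not self.degenerate:
            slope = (self.mu_tumor - self.mu_normal) / self.var
            const = (self.mu_tumor**2 - self.mu_normal**2) / (2.0 * self.var)
            return slope * x - const + np.log(self.prior_tumor / self.prior_normal)
        if self.mu_tumor == self.mu_normal:
            return np.zeros_like(x)
        # zero pooled variance: infinitely confident by side of the midpoint
        mid = 0.5 * (self.mu_tumor + self.mu_normal)
        side = np.sign((x - mid) * np.sign(self.mu_tumor - self.mu_normal))
        return np.where(side > 0, np.inf, np.where(side < 0, -np.inf, 0.0))

    @property
    def boundary(self) -> float:
        """x at which the score crosses zero (decision boundary)."""
        if self.degenerate or self.mu_tumor == self.mu_normal:
            return 0.5 * (self.mu_tumor + self.mu_normal)
        return 0.5 * (self.mu_tumor + self.mu_normal) - self.var * np.log(
            self.prior_tumor / self.prior_normal
        ) / (self.mu_tumor - self.mu_normal)

    def to_dict(self) -> dict:
        return {
            "mu_tumor": self.mu_tumor,
            "mu_normal": self.mu_normal,
            "var": self.var,
            "prior_tumor": self.prior_tumor,
            "prior_normal": self.prior_normal,
        }


def fit_lda_1d(values, labels) -> LdaModel1D:
    """Fit the one-feature LDA: class means, pooled variance, priors."""
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    xp, xn = x[y], x[~y]
    mu_p, mu_n = float(xp.mean()), float(xn.mean())
    ss = float(((xp - mu_p) ** 2).sum() + ((xn - mu_n) ** 2).sum())
    var = ss / (len(x) - 2) if len(x) > 2 else 0.0
    return LdaModel1D(
        mu_tumor=mu_p,
        mu_normal=mu_n,
        var=var,
        prior_tumor=n_pos / len(x),
        prior_normal=n_neg / len(x),
    )


# ---------------------------------------------------------------------------
# ROC / cross-validated AUC


def roc_auc(scores, labels) -> float:
    """AUC as the cross-class pair statistic P(s_tumor > s_normal) + P(tie)/2.

    Computed from midranks (equivalent to the Mann-Whitney U over n1*n2).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(s)
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


@dataclass
class ModelEval:
    """Cross-validation summary for one smMIP model."""

    fold_aucs: list[float]
    skipped_folds: list[int] = field(default_factory=list)
    cum_undigested: int | None = None

    @property
    def cvauc(self) -> float:
        return float(np.mean(self.fold_aucs))


def cv_auc(values, labels, folds) -> ModelEval:
    """Per-fold held-out AUC of the single-feature LDA; cvAUC is their mean.

    Folds whose held-out part (or training part) contains a single class
    are skipped and recorded.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    folds = np.asarray(folds)
    aucs, skipped = [], []
    for f in sorted(set(folds.tolist())):
        test = folds == f
        train = ~test
        if len(set(y[test].tolist())) < 2 or len(set(y[train].tolist())) < 2:
            skipped.append(int(f))
            continue
        model = fit_lda_1d(x[train], y[train])
        aucs.append(roc_auc(model.score(x[test]), y[test]))
    if not aucs:
        raise ValueError("every fold was degenerate; cannot cross-validate")
    return ModelEval(fold_aucs=aucs, skipped_folds=skipped)


# ---------------------------------------------------------------------------
# smMIP selection


def cumulative_undigested_counts(counts: CountMatrix) -> pd.Series:
    """Per-smMIP summed counts over the undigested control samples."""
    und = counts.undigested_samples
    if not und:
        raise ValueError("no undigested samples in count matrix")
    return counts.counts.loc[und].sum(axis=0)


def filter_smmips(
    evals: Mapping[str, ModelEval],
    cum_undigested: pd.Series,
    min_cum_undigested: int = 1000,
    min_cvauc: float = 0.8,
) -> list[str]:
    """Keep smMIPs that are both efficient and discriminating.

    Efficiency: cumulative count over undigested samples >= 1000 (the probe
    captures well when nothing is digested).  Discrimination: cvAUC >= 0.8.
    Both thresholds inclusive.
    """
    return [
        pid
        for pid, ev in evals.items()
        if float(cum_undigested.get(pid, 0)) >= min_cum_undigested and ev.cvauc >= min_cvauc
    ]


def pick_best_tile(
    smmip_ids: Sequence[str],
    site_groups: Mapping[str, str],
    evals: Mapping[str, ModelEval],
    cum_undigested: pd.Series,
) -> list[str]:
    """One smMIP per CpG site: highest cvAUC wins.

    Ties broken by higher cumulative undigested count, then lexicographic
    smMIP id.
    """
    by_site: dict[str, list[str]] = {}
    for pid in smmip_ids:
        by_site.setdefault(site_groups[pid], []).append(pid)
    chosen = []
    for site in sorted(by_site):
        best = min(
            by_site[site],
            key=lambda pid: (-evals[pid].cvauc, -float(cum_undigested.get(pid, 0)), pid),
        )
        chosen.append(best)
    return chosen


# ---------------------------------------------------------------------------
# Cutoffs


def single_model_cutoff(scores, labels) -> float:
    """Score cutoff minimizing FP + FN for the rule score >= cutoff => tumor.

    Candidates are midpoints between adjacent distinct sorted scores plus a
    point below the minimum and above the maximum; among ties the largest
    cutoff is returned (favoring specificity).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    distinct = np.unique(s)
    candidates = np.concatenate(
        [[distinct[0] - 1.0], (distinct[:-1] + distinct[1:]) / 2.0, [distinct[-1] + 1.0]]
    )
    best_cut, best_err = None, None
    for c in candidates:
        pred = s >= c
        err = int((pred & ~y).sum() + (~pred & y).sum())
        if best_err is None or err < best_err or (err == best_err and c > best_cut):
            best_cut, best_err = float(c), err
    return best_cut


def ensemble_vote_cutoff(votes: np.ndarray, labels) -> int:
    """Vote threshold k maximizing accuracy of 'votes >= k => tumor'.

    Ties resolved toward the smallest k (favoring sensitivity).
    """
    votes = np.asarray(votes, dtype=bool)
    y = np.asarray(labels, dtype=bool)
    n_models = votes.shape[1]
    tallies = votes.sum(axis=1)
    best_k, best_acc = None, -1.0
    for k in range(1, n_models + 1):
        acc = float(((tallies >= k) == y).mean())
        if acc > best_acc:
            best_k, best_acc = k, acc
    return best_k


# ---------------------------------------------------------------------------
# Confusion metrics


@dataclass(frozen=True)
class ConfusionTable:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @classmethod
    def from_predictions(cls, predicted, actual) -> "ConfusionTable":
        p = np.asarray(predicted, dtype=bool)
        a = np.asarray(actual, dtype=bool)
        return cls(
            tp=int((p & a).sum()),
            tn=int((~p & ~a).sum()),
            fp=int((p & ~a).sum()),
            fn=int((~p & a).sum()),
        )


def confusion_metrics(table: ConfusionTable) -> dict[str, float]:
    """Sensitivity, specificity, accuracy and balanced accuracy.

    A metric with a zero denominator is NaN (explicitly undefined), as for
    a blood-only stratum that contains no positives.
    """

    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    sens = ratio(table.tp, table.tp + table.fn)
    spec = ratio(table.tn, table.tn + table.fp)
    total = table.tp + table.tn + table.fp + table.fn
    return {
        "sensitivity": sens,
        "specificity": spec,
        "accuracy": ratio(table.tp + table.tn, total),
        "balanced_accuracy": (sens + spec) / 2.0,
    }


# ---------------------------------------------------------------------------
# Ensemble estimator


class EnsembleLdaClassifier(ClassifierMixin, BaseEstimator):
    """Ensemble of per-feature 1-D LDA models with a vote threshold.

    ``fit`` expects a samples x smMIPs DataFrame of (normalized) counts and
    binary labels (1 = tumor).  Fit-time keyword metadata:

    * ``cum_undigested`` — per-column cumulative counts over undigested
      samples, for the efficiency filter;
    * ``site_groups`` — column -> CpG-site id, for double-tile resolution
      (defaults to one site per column);
    * ``strata`` — labels for fold stratification (defaults to ``y``).

    Fitted attributes: ``included_smmips_``, ``models_``, ``cutoffs_``,
    ``vote_threshold_``, ``evals_``, ``training_confusion_``,
    ``training_metrics_``.
    """

    def __init__(
        self,
        n_folds: int = 5,
        min_cvauc: float = 0.8,
        min_cum_undigested: int = 1000,
        random_state: int = 0,
    ):
        self.n_folds = n_folds
        self.min_cvauc = min_cvauc
        self.min_cum_undigested = min_cum_undigested
        self.random_state = random_state

    def fit(
        self,
        X: pd.DataFrame,
        y,
        cum_undigested: pd.Series | None = None,
        site_groups: Mapping[str, str] | None = None,
        strata=None,
    ):
        X = pd.DataFrame(X)
        y = np.asarray(y).astype(bool)
        if cum_undigested is None:
            raise ValueError("cum_undigested metadata is required for the efficiency filter")
        if site_groups is None:
            site_groups = {c: c for c in X.columns}
        if strata is None:
            strata = y.astype(int)
        self.classes_ = np.array([0, 1])
        self.folds_ = stratified_folds(strata, self.n_folds, self.random_state)

        self.evals_ = {}
        for col in X.columns:
            try:
                ev = cv_auc(X[col].to_numpy(), y, self.folds_)
            except ValueError:
                continue
            ev.cum_undigested = int(cum_undigested.get(col, 0))
            self.evals_[col] = ev

        surviving = filter_smmips(
            self.evals_, cum_undigested, self.min_cum_undigested, self.min_cvauc
        )
        if not surviving:
            raise ValueError(
                "no smMIP passed the efficiency/cvAUC filters; cannot build an ensemble"
            )
        self.included_smmips_ = pick_best_tile(
            surviving, site_groups, self.evals_, cum_undigested
        )

        self.models_ = {}
        self.cutoffs_ = {}
        for pid in self.included_smmips_:
            model = fit_lda_1d(X[pid].to_numpy(), y)
            self.models_[pid] = model
            self.cutoffs_[pid] = single_model_cutoff(model.score(X[pid].to_numpy()), y)

        votes = self._votes(X)
        self.vote_threshold_ = ensemble_vote_cutoff(votes.to_numpy(), y)
        pred = votes.sum(axis=1).to_numpy() >= self.vote_threshold_
        self.training_confusion_ = ConfusionTable.from_predictions(pred, y)
        self.training_metrics_ = confusion_metrics(self.training_confusion_)
        return self

    def _check_columns(self, X: pd.DataFrame) -> None:
        missing = [pid for pid in self.included_smmips_ if pid not in X.columns]
        if missing:
            raise ValueError(f"input lacks smMIP columns: {missing}")

    def _votes(self, X: pd.DataFrame) -> pd.DataFrame:
        self._check_columns(X)
        data = {
            pid: self.models_[pid].score(X[pid].to_numpy()) >= self.cutoffs_[pid]
            for pid in self.included_smmips_
        }
        return pd.DataFrame(data, index=X.index)

    def vote_counts(self, X: pd.DataFrame) -> pd.Series:
        return self._votes(pd.DataFrame(X)).sum(axis=1)

    def decision_function(self, X) -> np.ndarray:
        return self.vote_counts(X).to_numpy() - self.vote_threshold_

    def predict(self, X) -> np.ndarray:
        return (self.vote_counts(pd.DataFrame(X)).to_numpy() >= self.vote_threshold_).astype(int)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "params": self.get_params(),
            "included_smmips": list(self.included_smmips_),
            "models": {pid: m.to_dict() for pid, m in self.models_.items()},
            "cutoffs": {pid: float(c) for pid, c in self.cutoffs_.items()},
            "vote_threshold": int(self.vote_threshold_),
            "training_confusion": vars(self.training_confusion_),
            "training_metrics": self.training_metrics_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EnsembleLdaClassifier":
        est = cls(**d["params"])
        est.classes_ = np.array([0, 1])
        est.included_smmips_ = list(d["included_smmips"])
        est.models_ = {pid: LdaModel1D(**m) for pid, m in d["models"].items()}
        est.cutoffs_ = {pid: float(c) for pid, c in d["cutoffs"].items()}
        est.vote_threshold_ = int(d["vote_threshold"])
        est.training_confusion_ = ConfusionTable(**d["training_confusion"])
        est.training_metrics_ = dict(d["training_metrics"])
        est.evals_ = {}
        return est


# ---------------------------------------------------------------------------
# CountMatrix-level convenience


@dataclass
class TrainedModel:
    """Fitted ensemble plus everything needed to score new count matrices."""

    classifier: EnsembleLdaClassifier
    reference_ids: list[str]
    scale: str  # "normalized" | "raw"
    seed: int

    def to_json(self, path) -> None:
        payload = {
            "classifier": self.classifier.to_dict(),
            "reference_ids": self.reference_ids,
            "scale": self.scale,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TrainedModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            classifier=EnsembleLdaClassifier.from_dict(d["classifier"]),
            reference_ids=list(d["reference_ids"]),
            scale=d["scale"],
            seed=int(d["seed"]),
        )

    def _features(self, counts: CountMatrix) -> pd.DataFrame:
        if self.scale == "normalized":
            return normalize(counts, self.reference_ids).values
        return counts.counts.astype(float)

    def predict(self, counts: CountMatrix) -> pd.DataFrame:
        """Per-sample vote count and tumor/non-tumor call."""
        X = self._features(counts)
        votes = self.classifier.vote_counts(X)
        return pd.DataFrame(
            {
                "votes": votes.astype(int),
                "prediction": np.where(
                    votes >= self.classifier.vote_threshold_, "tumor", "non-tumor"
                ),
            },
            index=counts.counts.index,
        )


def train_ensemble(
    counts: CountMatrix,
    scale: str = "normalized",
    reference_ids: Sequence[str] | None = None,
    n_folds: int = 5,
    min_cvauc: float = 0.8,
    min_cum_undigested: int = 1000,
    seed: int = 0,
) -> TrainedModel:
    """Build the full ensemble from a QC-filtered count matrix.

    Digested samples form the training set (tumor vs normal + blood, blood
    in the negative class); undigested controls supply the efficiency
    filter counts.  LDA operates on reference-normalized counts by default
    (``scale="raw"`` switches to raw counts).
    """
    if scale not in ("normalized", "raw"):
        raise ValueError(f"unknown scale {scale!r}")
    refs = list(reference_ids) if reference_ids is not None else counts.reference_ids
    cum_und = cumulative_undigested_counts(counts)
    digested = counts.digested_samples
    sub = counts.subset(samples=digested)
    meta = sub.sample_meta
    y = (meta["condition"] == "tumor").to_numpy()
    strata = (meta["tissue"].astype(str) + "|" + meta["condition"].astype(str)).to_numpy()

    if scale == "normalized":
        X_all = normalize(sub, refs).values
    else:
        X_all = sub.counts.astype(float)
    cpg = sub.cpg_ids
    site_groups = {pid: sub.smmip_meta.loc[pid, "target_id"] for pid in cpg}

    clf = EnsembleLdaClassifier(
        n_folds=n_folds,
        min_cvauc=min_cvauc,
        min_cum_undigested=min_cum_undigested,
        random_state=seed,
    )
    clf.fit(
        X_all[cpg], y, cum_undigested=cum_und, site_groups=site_groups, strata=strata
    )
    return TrainedModel(classifier=clf, reference_ids=refs, scale=scale, seed=seed)
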