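"""Training and evaluation of the STR dosage classifiers.

Two random-intercept logistic models are trained against the shared
pool of normal 1:1 genotypes: one for the trisomic 2:1 pattern (the
shorter allele duplicated) and one for 1:2 (the longer allele
duplicated).  Each model's probability cutoff is the midpoint between
the lowest fitted probability among trisomic training genotypes and
the highest among normal ones, so a non-overlapping training set
yields zero training false calls by construction.

The classical alternative — flagging on the raw height ratio alone at
fixed cutoffs (1.94 for 2:1, 0.94 for 1:2) — is retained both as a
fallback for markers outside the regression (DYS448) and as the
comparison baseline in ROC evaluation.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Sequence

import numpy as np
from scipy.stats import pearsonr, rankdata

from .glmm import GlmmFit, GlmmSpec, fit_glmm, predict_probability
from .panel import REGRESSION_EXCLUDED
from .tables import DiallelicObservation

MODEL_FORMAT_VERSION = 1

DEFAULT_RATIO_THRESHOLD_21 = 1.94
DEFAULT_RATIO_THRESHOLD_12 = 0.94


class ClassifierError(ValueError):
    """Raised for unusable training data or model files."""


@dataclass(frozen=True)
class ThresholdResult:
    """Probability cutoff with its defining endpoints."""

    cutoff: float
    min_trisomic_p: float
    max_normal_p: float
    overlap: bool  # min trisomic p <= max normal p


@dataclass
class ClassifierModel:
    """The paired 2:1 / 1:2 dosage classifiers and their cutoffs."""

    fit_21: GlmmFit
    fit_12: GlmmFit
    threshold_21: float
    threshold_12: float
    ratio_threshold_21: float = DEFAULT_RATIO_THRESHOLD_21
    ratio_threshold_12: float = DEFAULT_RATIO_THRESHOLD_12
    training_summary: dict[str, int] = field(default_factory=dict)
    threshold_detail_21: ThresholdResult | None = None
    threshold_detail_12: ThresholdResult | None = None
    #: per-marker normals' ratio-vs-size-difference lines (for
    #: decay-adjusting triallelic patterns downstream)
    decay_lines: dict[str, "MarkerCorrelation"] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold_21 < 1.0 and 0.0 < self.threshold_12 < 1.0):
            raise ClassifierError("probability thresholds must lie in (0, 1)")
        if not self.ratio_threshold_12 < 1.0 < self.ratio_threshold_21:
            raise ClassifierError("ratio thresholds must bracket 1.0")

    def per_marker_intercepts(self) -> dict[str, dict[str, float]]:
        """Field-use representation: per marker, the population fixed
        effects with the marker's conditional mode folded into the
        intercept, for each model."""
        out: dict[str, dict[str, float]] = {}
        for tag, fit in (("2:1", self.fit_21), ("1:2", self.fit_12)):
            for marker, mode in fit.conditional_modes.items():
                entry = out.setdefault(marker, {})
                for term, b in fit.beta.items():
                    key = f"{tag}:{term}"
                    entry[key] = b + mode if term == "intercept" else b
        return out


@dataclass(frozen=True)
class MarkerClassification:
    """Per-observation verdict of one classification method."""

    observation: DiallelicObservation
    p_21: float
    p_12: float
    call: str  # normal | trisomic_2_1 | trisomic_1_2 | conflict
    method: str  # regression | ratio_only


def compute_threshold(
    fit: GlmmFit, training: Sequence[DiallelicObservation]
) -> ThresholdResult:
    """Midpoint cutoff between the trisomic and normal probability extremes.

    cutoff = (min fitted p over trisomic + max fitted p over normal) / 2.
    Overlapping classes still return the midpoint but set ``overlap``.
    """
    p_tri = [
        predict_probability(fit, o)
        for o in training
        if o.label.startswith("trisomic")
    ]
    p_norm = [
        predict_probability(fit, o) for o in training if o.label == "normal_1_1"
    ]
    if not p_tri or not p_norm:
        raise ClassifierError("threshold needs both trisomic and normal fitted p")
    lo, hi = min(p_tri), max(p_norm)
    return ThresholdResult(
        cutoff=(lo + hi) / 2.0,
        min_trisomic_p=lo,
        max_normal_p=hi,
        overlap=lo <= hi,
    )


def train(
    training: Sequence[DiallelicObservation],
    spec: GlmmSpec = GlmmSpec(),
    ratio_threshold_21: float = DEFAULT_RATIO_THRESHOLD_21,
    ratio_threshold_12: float = DEFAULT_RATIO_THRESHOLD_12,
) -> ClassifierModel:
    """Train the paired dosage classifiers.

    The 2:1 model is fitted on normals + trisomic 2:1 genotypes, the
    1:2 model on the same normals + trisomic 1:2 genotypes.
    Observations from markers outside the regression set (DYS448) are
    dropped with a warning; a class with zero observations is an error.
    """
    usable = [o for o in training if o.marker not in REGRESSION_EXCLUDED]
    if len(usable) < len(training):
        warnings.warn(
            "training rows from regression-excluded markers were dropped",
            stacklevel=2,
        )
    normals = [o for o in usable if o.label == "normal_1_1"]
    tri21 = [o for o in usable if o.label == "trisomic_2_1"]
    tri12 = [o for o in usable if o.label == "trisomic_1_2"]
    for name, group in (("normal_1_1", normals), ("trisomic_2_1", tri21),
                        ("trisomic_1_2", tri12)):
        if not group:
            raise ClassifierError(f"training has no {name} observations")
    data_21 = normals + tri21
    data_12 = normals + tri12
    fit_21 = fit_glmm(data_21, spec)
    fit_12 = fit_glmm(data_12, spec)
    thr_21 = compute_threshold(fit_21, data_21)
    thr_12 = compute_threshold(fit_12, data_12)
    return ClassifierModel(
        fit_21=fit_21,
        fit_12=fit_12,
        threshold_21=thr_21.cutoff,
        threshold_12=thr_12.cutoff,
        ratio_threshold_21=ratio_threshold_21,
        ratio_threshold_12=ratio_threshold_12,
        training_summary={
            "normal_1_1": len(normals),
            "trisomic_2_1": len(tri21),
            "trisomic_1_2": len(tri12),
        },
        threshold_detail_21=thr_21,
        threshold_detail_12=thr_12,
        decay_lines=correlation_by_marker(normals),
    )


def classify(
    model: ClassifierModel, obs: DiallelicObservation
) -> MarkerClassification:
    """Regression classification of one diallelic observation.

    Markers outside the regression set fall back to ratio-only
    classification.  ``conflict`` (both models positive) signals an
    input problem and is never auto-resolved.
    """
    if obs.marker in REGRESSION_EXCLUDED:
        return classify_ratio_only(model, obs)
    p_21 = predict_probability(model.fit_21, obs)
    p_12 = predict_probability(model.fit_12, obs)
    hit_21 = p_21 > model.threshold_21
    hit_12 = p_12 > model.threshold_12
    call = (
        "conflict"
        if (hit_21 and hit_12)
        else "trisomic_2_1"
        if hit_21
        else "trisomic_1_2"
        if hit_12
        else "normal"
    )
    return MarkerClassification(
        observation=obs, p_21=p_21, p_12=p_12, call=call, method="regression"
    )


def classify_ratio_only(
    model: ClassifierModel, obs: DiallelicObservation
) -> MarkerClassification:
    """Height-ratio-only classification at the fixed 1.94 / 0.94 cutoffs.

    The boundary is closed: a ratio exactly at a cutoff is flagged.
    """
    if obs.height_ratio >= model.ratio_threshold_21:
        call = "trisomic_2_1"
    elif obs.height_ratio <= model.ratio_threshold_12:
        call = "trisomic_1_2"
    else:
        call = "normal"
    return MarkerClassification(
        observation=obs,
        p_21=math.nan,
        p_12=math.nan,
        call=call,
        method="ratio_only",
    )


# ---------------------------------------------------------------------------
# evaluation


@dataclass(frozen=True)
class RocResult:
    """ROC curve with the full-sensitivity operating point."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    full_sensitivity_threshold: float
    fp_at_full_sensitivity: int
    specificity_at_full_sensitivity: float


def evaluate_roc(scores: Sequence[tuple[float, int]]) -> RocResult:
    """ROC analysis of (score, label) pairs; higher score = more positive.

    AUC is the Mann--Whitney concordance probability with midrank tie
    handling.  The full-sensitivity operating point is the cutoff at
    the lowest positive score (every positive called), reported with
    its false-positive count and specificity.
    """
    s = np.array([x for x, _ in scores], float)
    y = np.array([int(l) for _, l in scores])
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ClassifierError("ROC needs both classes")
    ranks = rankdata(s)  # midranks
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    thresholds = np.concatenate([[np.inf], np.unique(s)[::-1]])
    tpr = np.array([(s[y == 1] >= t).mean() for t in thresholds])
    fpr = np.array([(s[y == 0] >= t).mean() for t in thresholds])
    t_full = float(s[y == 1].min())
    fp = int((s[y == 0] >= t_full).sum())
    return RocResult(
        fpr=fpr,
        tpr=tpr,
        auc=float(auc),
        full_sensitivity_threshold=t_full,
        fp_at_full_sensitivity=fp,
        specificity_at_full_sensitivity=1.0 - fp / n_neg,
    )


@dataclass(frozen=True)
class EvaluationSummary:
    """Confusion counts of one classification method on labeled data."""

    method: str
    n: int
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else math.nan

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else math.nan


def evaluate(
    model: ClassifierModel,
    observations: Sequence[DiallelicObservation],
    method: str = "regression",
) -> EvaluationSummary:
    """Confusion summary against the observations' truth labels.

    An observation is counted positive when its label is trisomic; a
    predicted trisomy of the wrong orientation counts as a false call
    on both sides (missed truth, spurious positive).
    """
    fn_ = classify if method == "regression" else classify_ratio_only
    tp = fp = tn = fn = 0
    for o in observations:
        truth_pos = o.label.startswith("trisomic")
        call = fn_(model, o).call
        if truth_pos:
            if call == o.label:
                tp += 1
            else:
                fn += 1
        else:
            if call == "normal":
                tn += 1
            else:
                fp += 1
    return EvaluationSummary(
        method=method, n=len(observations), tp=tp, fp=fp, tn=tn, fn=fn
    )


@dataclass(frozen=True)
class MarkerCorrelation:
    """Per-marker ratio-vs-size-difference association among normals."""

    marker: str
    n: int
    r: float  # NaN when degenerate (constant covariate)
    slope: float
    intercept: float


def correlation_by_marker(
    observations: Sequence[DiallelicObservation], min_count: int = 3
) -> dict[str, MarkerCorrelation]:
    """Pearson r and least-squares line per marker, normals only.

    Markers with fewer than ``min_count`` normal observations are
    absent from the result; a degenerate marker (constant size
    difference or ratio) is reported with ``r = NaN``.
    """
    groups: dict[str, list[DiallelicObservation]] = {}
    for o in observations:
        if o.label == "normal_1_1":
            groups.setdefault(o.marker, []).append(o)
    out: dict[str, MarkerCorrelation] = {}
    for marker, obs in groups.items():
        if len(obs) < min_count:
            continue
        x = np.array([o.size_difference for o in obs])
        yv = np.array([o.height_ratio for o in obs])
        if np.ptp(x) == 0 or np.ptp(yv) == 0:
            out[marker] = MarkerCorrelation(marker, len(obs), math.nan, 0.0,
                                            float(yv.mean()))
            continue
        r, _ = pearsonr(x, yv)
        slope, intercept = np.polyfit(x, yv, 1)
        out[marker] = MarkerCorrelation(
            marker, len(obs), float(r), float(slope), float(intercept)
        )
    return out


# ---------------------------------------------------------------------------
# serialization


def _fit_to_doc(fit: GlmmFit) -> dict:
    return {
        "fixed_terms": list(fit.spec.fixed_terms),
        "grouping": fit.spec.grouping,
        "beta": fit.beta,
        "sigma_b": fit.sigma_b,
        "conditional_modes": fit.conditional_modes,
        "logLik": fit.logLik,
        "deviance_resid": fit.deviance_resid,
        "aic": fit.aic,
        "bic": fit.bic,
        "df_residual": fit.df_residual,
        "n_obs": fit.n_obs,
        "converged": fit.converged,
        "separation_flag": fit.separation_flag,
    }


def _fit_from_doc(doc: dict) -> GlmmFit:
    spec = GlmmSpec(tuple(doc["fixed_terms"]), doc["grouping"])
    return GlmmFit(
        spec=spec,
        beta={k: float(v) for k, v in doc["beta"].items()},
        sigma_b=float(doc["sigma_b"]),
        conditional_modes={k: float(v) for k, v in doc["conditional_modes"].items()},
        logLik=float(doc["logLik"]),
        deviance_resid=float(doc["deviance_resid"]),
        aic=float(doc["aic"]),
        bic=float(doc["bic"]),
        df_residual=int(doc["df_residual"]),
        n_obs=int(doc["n_obs"]),
        converged=bool(doc["converged"]),
        separation_flag=bool(doc["separation_flag"]),
    )


def save_model(model: ClassifierModel, dest: str | Path | IO[str]) -> None:
    """Serialize the classifier to versioned JSON text."""
    doc = {
        "format": "qfpcr-classifier",
        "format_version": MODEL_FORMAT_VERSION,
        "fit_21": _fit_to_doc(model.fit_21),
        "fit_12": _fit_to_doc(model.fit_12),
        "threshold_21": model.threshold_21,
        "threshold_12": model.threshold_12,
        "ratio_threshold_21": model.ratio_threshold_21,
        "ratio_threshold_12": model.ratio_threshold_12,
        "training_summary": model.training_summary,
        "per_marker_intercepts": model.per_marker_intercepts(),
        "decay_lines": {
            m: {"n": c.n, "r": c.r, "slope": c.slope, "intercept": c.intercept}
            for m, c in model.decay_lines.items()
        },
    }
    if hasattr(dest, "write"):
        json.dump(doc, dest, indent=1)
    else:
        with open(dest, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1)


def load_model(source: str | Path | IO[str]) -> ClassifierModel:
    """Load a serialized classifier; classification round-trips exactly."""
    if hasattr(source, "read"):
        doc = json.load(source)
    else:
        with open(source, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
    if doc.get("format") != "qfpcr-classifier":
        raise ClassifierError("not a classifier model file")
    if doc.get("format_version") != MODEL_FORMAT_VERSION:
        raise ClassifierError(
            f"unsupported model format version {doc.get('format_version')}"
        )
    return ClassifierModel(
        fit_21=_fit_from_doc(doc["fit_21"]),
        fit_12=_fit_from_doc(doc["fit_12"]),
        threshold_21=float(doc["threshold_21"]),
        threshold_12=float(doc["threshold_12"]),
        ratio_threshold_21=float(doc["ratio_threshold_21"]),
        ratio_threshold_12=float(doc["ratio_threshold_12"]),
        training_summary={
            k: int(v) for k, v in doc.get("training_summary", {}).items()
        },
        decay_lines={
            m: MarkerCorrelation(
                m, int(d["n"]), float(d["r"]), float(d["slope"]),
                float(d["intercept"]),
            )
            for m, d in doc.get("decay_lines", {}).items()
        },
    )
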