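"""Signed-signature scoring, calibration and stratification.

The per-sample signature score is a signed z-mean: every gene is z-scored
across samples, and the score is mean(z of up genes) minus mean(z of down
genes). This is the simplest signed score consistent with calling samples
signature-positive or -negative; an empty side contributes 0.

Pathway-activity calibration is a pure location shift that anchors the
median of a mutant reference cohort at a target value (default 0.15);
"low" activity is then a calibrated score below that target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ExpressionMatrix, SignedSignature

logger = logging.getLogger("sigrank")

__all__ = [
    "ScoreVector",
    "CalibrationParams",
    "score_signature",
    "dichotomize",
    "calibrate_activity",
    "pearson_with_p",
    "stratify_pten_p53",
]


@dataclass
class ScoreVector:
    """Per-sample scores, with optional binary labels after dichotomization."""

    sample_ids: list[str]
    score: np.ndarray
    label: np.ndarray | None = None  # 1 = positive, 0 = negative

    def __post_init__(self) -> None:
        self.score = np.asarray(self.score, dtype=float)
        if len(self.sample_ids) != self.score.size:
            raise ValueError("sample_ids and score must align")
        if not np.isfinite(self.score).all():
            raise ValueError("scores must be finite")
        if self.label is not None:
            self.label = np.asarray(self.label, dtype=int)
            if self.label.size != self.score.size:
                raise ValueError("labels must align with scores")

    def __len__(self) -> int:
        return self.score.size

    def to_frame(self) -> pd.DataFrame:
        d = {"sample": self.sample_ids, "score": self.score}
        if self.label is not None:
            d["label"] = self.label
        return pd.DataFrame(d)


@dataclass(frozen=True)
class CalibrationParams:
    """Location shift anchoring a reference median at ``reference_value``."""

    offset: float
    reference_value: float = 0.15


def score_signature(matrix: ExpressionMatrix, sig: SignedSignature) -> ScoreVector:
    """Signed z-mean score of a signature over the samples of a matrix.

    Genes are z-scored across samples (sample SD, ddof=1); the score is the
    mean z of up genes minus the mean z of down genes. Signature genes
    absent from the matrix are skipped with a log message, as are genes
    with zero variance (their z-score is undefined).
    """
    if matrix.n_samples < 2:
        raise ValueError("z-scoring needs >= 2 samples")
    present_up = [g for g in sig.up if g in matrix.values.index]
    present_down = [g for g in sig.down if g in matrix.values.index]
    missing = len(sig.up) - len(present_up) + len(sig.down) - len(present_down)
    if missing:
        logger.warning("signature %r: %d gene(s) absent from matrix, skipped", sig.name, missing)
    if not present_up and not present_down:
        raise ValueError(f"no gene of signature {sig.name!r} present in the matrix")

    def z_mean(genes: list[str]) -> np.ndarray:
        if not genes:
            return np.zeros(matrix.n_samples)
        sub = matrix.values.loc[genes].to_numpy()
        sd = sub.std(axis=1, ddof=1)
        keep = sd > 0
        if not keep.all():
            logger.warning("%d zero-variance signature gene(s) skipped", int((~keep).sum()))
        if not keep.any():
            return np.zeros(matrix.n_samples)
        sub = sub[keep]
        z = (sub - sub.mean(axis=1, keepdims=True)) / sd[keep][:, None]
        return z.mean(axis=0)

    score = z_mean(sorted(present_up)) - z_mean(sorted(present_down))
    return ScoreVector(matrix.sample_ids, score)


def dichotomize(scores: ScoreVector, rule: str = "median", q: float | None = None, threshold: float | None = None) -> ScoreVector:
    """Assign binary labels to scores.

    Rules: ``median`` (positive = strictly above the median),
    ``top_quantile`` (positive = the ceil-free top fraction q, ties to the
    negative class so the positive class never exceeds q of samples),
    ``bottom_quantile`` (positive = bottom fraction q), and ``threshold``
    (positive = score strictly above c). Ties at any cut point go to the
    negative class.
    """
    s = scores.score
    if rule == "median":
        cut = float(np.median(s))
        label = (s > cut).astype(int)
    elif rule in ("top_quantile", "bottom_quantile"):
        if q is None or not (0 < q < 1):
            raise ValueError("quantile rule needs q in (0,1)")
        k = int(np.floor(q * s.size))
        label = np.zeros(s.size, dtype=int)
        if k > 0:
            order = np.argsort(s, kind="stable")
            chosen = order[-k:] if rule == "top_quantile" else order[:k]
            # ties to negative: drop chosen entries whose score equals the
            # score just outside the selected block
            if rule == "top_quantile" and k < s.size:
                boundary = s[order[-k - 1]]
                chosen = chosen[s[chosen] > boundary]
            elif rule == "bottom_quantile" and k < s.size:
                boundary = s[order[k]]
                chosen = chosen[s[chosen] < boundary]
            label[chosen] = 1
    elif rule == "threshold":
        if threshold is None:
            raise ValueError("threshold rule needs a threshold value")
        label = (s > threshold).astype(int)
    else:
        raise ValueError(f"unknown dichotomization rule {rule!r}")
    return ScoreVector(scores.sample_ids, s.copy(), label)


def calibrate_activity(
    scores: ScoreVector,
    mutant_reference_scores,
    target: float = 0.15,
) -> tuple[ScoreVector, CalibrationParams]:
    """Shift scores so the mutant-reference median lands on ``target``.

    Only a location adjustment: anchoring one statistic (the reference
    median) determines an offset, nothing more. Ordering is preserved.
    """
    ref = np.asarray(mutant_reference_scores, dtype=float)
    if ref.size == 0:
        raise ValueError("empty mutant reference")
    offset = float(target - np.median(ref))
    shifted = ScoreVector(scores.sample_ids, scores.score + offset, scores.label)
    logger.info("calibration offset %.4f (reference median -> %.3f)", offset, target)
    return shifted, CalibrationParams(offset=offset, reference_value=target)


def pearson_with_p(x, y) -> tuple[float, float]:
    """Pearson correlation with the two-sided t-test p-value.

    p from t = r sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def stratify_pten_p53(
    pten_expression: ScoreVector,
    p53_activity: ScoreVector,
    pten_low_quantile: float = 0.25,
    reference_value: float = 0.15,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Joint Pten / p53-activity status per sample.

    Pten-low = bottom ``pten_low_quantile`` of Pten expression within the
    analyzed samples; p53-low = calibrated p53 pathway activity below the
    reference value. Returns a per-sample status table (status in
    {both-low, pten-low-only, p53-low-only, neither}) and the group
    frequencies including the marginals.
    """
    if list(pten_expression.sample_ids) != list(p53_activity.sample_ids):
        raise ValueError("sample sets of Pten expression and p53 activity differ")
    if not (0 < pten_low_quantile < 1):
        raise ValueError("pten_low_quantile must be in (0,1)")
    n = len(pten_expression)
    pten_low = dichotomize(pten_expression, "bottom_quantile", q=pten_low_quantile).label.astype(bool)
    p53_low = p53_activity.score < reference_value

    status = np.where(
        pten_low & p53_low,
        "both-low",
        np.where(pten_low, "pten-low-only", np.where(p53_low, "p53-low-only", "neither")),
    )
    table = pd.DataFrame(
        {
            "sample": pten_expression.sample_ids,
            "pten_low": pten_low.astype(int),
            "p53_low": p53_low.astype(int),
            "status": status,
        }
    )
    freqs = {
        "pten_low": float(pten_low.mean()),
        "p53_low": float(p53_low.mean()),
        "both_low": float((pten_low & p53_low).mean()),
        "pten_low_only": float((pten_low & ~p53_low).mean()),
        "p53_low_only": float((~pten_low & p53_low).mean()),
        "neither": float((~pten_low & ~p53_low).mean()),
    }
    logger.info(
        "stratification over %d samples: %.1f%% Pten-low, %.1f%% p53-low, %.1f%% both",
        n, 100 * freqs["pten_low"], 100 * freqs["p53_low"], 100 * freqs["both_low"],
    )
    return table, freqs
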