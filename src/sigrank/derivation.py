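"""Two-group differential-expression signature derivation.

The chain is: per-gene one-way ANOVA (with exactly two groups this is the
equal-variance t-test, F = t^2), Benjamini-Hochberg FDR adjustment, and a
fold-change filter. A gene enters the signed signature when its q-value is
below the FDR threshold AND its absolute log2 fold change strictly exceeds
log2 of the linear fold-change threshold (">twofold" means |dlog2| > 1 on
log2-scale data).

Group A is the lexicographically first group label unless overridden;
log2FC = mean(A) - mean(B). Zero-variance genes are flagged degenerate and
assigned p = 1 so genome-wide scans never abort.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ExpressionMatrix, SignedSignature

logger = logging.getLogger("sigrank")

__all__ = ["anova_per_gene", "bh_fdr", "derive_signature", "derive_from_matrix"]


def anova_per_gene(
    matrix: ExpressionMatrix,
    groups: dict[str, list[str]] | None = None,
    group_a: str | None = None,
    welch: bool = False,
) -> pd.DataFrame:
    """Per-gene two-group ANOVA over a labelled expression matrix.

    Parameters
    ----------
    matrix : ExpressionMatrix
        Log2 expression; if ``groups`` is None, ``matrix.group_labels``
        must define exactly two groups with >= 2 samples each.
    group_a : str, optional
        Which group is "A" in log2FC = mean(A) - mean(B). Default: first
        label lexicographically.
    welch : bool
        Use Welch's unequal-variance t-test instead of the pooled-variance
        ANOVA (F is then the squared Welch t, p from its t distribution).

    Returns
    -------
    DataFrame indexed by gene with columns ``log2fc``, ``F``, ``p``,
    ``degenerate`` (zero pooled variance).
    """
    if groups is None:
        groups = matrix.groups()
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {sorted(groups)}")
    labels = sorted(groups)
    if group_a is None:
        group_a = labels[0]
    if group_a not in groups:
        raise ValueError(f"group_a {group_a!r} not among {labels}")
    group_b = labels[0] if group_a == labels[1] else labels[1]
    a_ids, b_ids = groups[group_a], groups[group_b]
    if len(a_ids) < 2 or len(b_ids) < 2:
        raise ValueError("each group needs >= 2 samples")
    logger.info(
        "per-gene ANOVA: A=%s (n=%d) vs B=%s (n=%d), %d genes%s",
        group_a, len(a_ids), group_b, len(b_ids), matrix.n_genes,
        " [Welch]" if welch else "",
    )

    xa = matrix.values[a_ids].to_numpy()
    xb = matrix.values[b_ids].to_numpy()
    na, nb = xa.shape[1], xb.shape[1]
    ma, mb = xa.mean(axis=1), xb.mean(axis=1)
    va, vb = xa.var(axis=1, ddof=1), xb.var(axis=1, ddof=1)
    log2fc = ma - mb

    if welch:
        denom = va / na + vb / nb
        degenerate = denom == 0
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (ma - mb) / np.sqrt(denom)
            df = denom**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        F = t**2
        p = 2 * stats.t.sf(np.abs(t), df)
    else:
        # one-way fixed-effects ANOVA, two groups: F = MS_between / MS_within
        n = na + nb
        grand = (na * ma + nb * mb) / n
        ss_between = na * (ma - grand) ** 2 + nb * (mb - grand) ** 2
        ss_within = va * (na - 1) + vb * (nb - 1)
        ms_within = ss_within / (n - 2)
        degenerate = ms_within == 0
        with np.errstate(divide="ignore", invalid="ignore"):
            F = ss_between / ms_within
        p = stats.f.sf(F, 1, n - 2)

    F = np.where(degenerate, np.nan, F)
    p = np.where(degenerate, 1.0, p)
    n_deg = int(degenerate.sum())
    if n_deg:
        logger.warning("%d gene(s) with zero within-group variance; p set to 1", n_deg)
    return pd.DataFrame(
        {"log2fc": log2fc, "F": F, "p": p, "degenerate": degenerate},
        index=matrix.values.index,
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * m / j over sorted p, which enforces
    monotonicity; q is clipped to [0, 1] and returned in input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def derive_signature(
    de: pd.DataFrame,
    q_threshold: float = 0.05,
    fc_threshold: float = 2.0,
    name: str = "signature",
) -> SignedSignature:
    """Apply the FDR and fold-change filters to a DE table.

    ``de`` must carry ``log2fc`` and either ``q`` or ``p`` (q computed by
    BH when absent). Up = q < q_threshold and log2fc > log2(fc_threshold);
    down analogously with the negative bound. Both inequalities strict.
    An empty signature is returned with a warning, not an error.
    """
    if not (0 < q_threshold < 1):
        raise ValueError("q_threshold must be in (0,1)")
    if fc_threshold <= 0:
        raise ValueError("fc_threshold must be positive")
    de = de.copy()
    if "q" not in de.columns:
        de["q"] = bh_fdr(de["p"].to_numpy())
    lfc_cut = np.log2(fc_threshold)
    sig = de["q"] < q_threshold
    up = de.index[sig & (de["log2fc"] > lfc_cut)]
    down = de.index[sig & (de["log2fc"] < -lfc_cut)]
    signature = SignedSignature(name, set(up), set(down))
    if len(signature) == 0:
        logger.warning("derived signature %r is empty at q<%g, fc>%g", name, q_threshold, fc_threshold)
    else:
        logger.info(
            "derived signature %r: %d up, %d down (q<%g, |log2fc|>%g)",
            name, len(signature.up), len(signature.down), q_threshold, lfc_cut,
        )
    return signature


def derive_from_matrix(
    matrix: ExpressionMatrix,
    q_threshold: float = 0.05,
    fc_threshold: float = 2.0,
    name: str = "signature",
    group_a: str | None = None,
    welch: bool = False,
) -> tuple[SignedSignature, pd.DataFrame]:
    """Full chain: ANOVA -> BH FDR -> fold-change filter.

    Returns the signature and the annotated DE table (with ``q`` and
    ``direction`` columns).
    """
    de = anova_per_gene(matrix, group_a=group_a, welch=welch)
    de["q"] = bh_fdr(de["p"].to_numpy())
    signature = derive_signature(de, q_threshold, fc_threshold, name)
    direction = pd.Series("none", index=de.index)
    direction.loc[list(signature.up)] = "up"
    direction.loc[list(signature.down)] = "down"
    de["direction"] = direction
    return signature, de
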