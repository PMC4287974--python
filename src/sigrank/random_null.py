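"""Composition-matched random-signature null for prognostic signatures.

A prognostic signature could stratify patients "by chance": to test this,
N random signed signatures with the same composition (same numbers of up
and down genes) are drawn from the expression universe, each is pushed
through the identical score -> median dichotomization -> survival chain,
and the real signature is ranked among them.

Significance of each signature is gated on the Gehan-Wilcoxon p-value;
the hazard ratio comes from a univariate Cox fit on the binary label.
Both are stored per signature, so the gate is switchable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import ClinicalCohort, ExpressionMatrix, SignedSignature
from .scoring import dichotomize, score_signature
from .survival import cox_univariate, two_sample_test

logger = logging.getLogger("sigrank")

__all__ = [
    "generate_random_signatures",
    "evaluate_signature_prognosis",
    "NullRankResult",
    "null_rank",
]


def generate_random_signatures(
    universe,
    n_up: int,
    n_down: int,
    n_signatures: int,
    rng: np.random.Generator,
) -> list[SignedSignature]:
    """Draw composition-matched random signed signatures.

    Each signature samples ``n_up + n_down`` distinct genes uniformly
    without replacement from the universe; the first ``n_up`` become the
    up set. Draws are independent across signatures.
    """
    universe = list(universe)
    k = n_up + n_down
    if len(universe) < k:
        raise ValueError(f"universe of {len(universe)} genes too small for {k}-gene signatures")
    sigs = []
    for i in range(n_signatures):
        picked = rng.choice(len(universe), size=k, replace=False)
        genes = [universe[j] for j in picked]
        sigs.append(SignedSignature(f"random{i:04d}", set(genes[:n_up]), set(genes[n_up:])))
    return sigs


def evaluate_signature_prognosis(
    sig: SignedSignature,
    matrix: ExpressionMatrix,
    cohort: ClinicalCohort,
    test_method: str = "gehan_wilcoxon",
) -> tuple[float, float]:
    """(HR, p) for one signature over one cohort.

    Chain: signed z-mean score -> median dichotomization (positive = high
    score) -> Gehan-Wilcoxon p between label groups and Cox HR on the
    binary label. A degenerate dichotomization (all samples one class)
    yields (NaN, 1.0), counted non-significant.
    """
    common = [s for s in matrix.sample_ids if s in set(cohort.sample_ids)]
    if not common:
        raise ValueError("matrix and cohort share no samples")
    sub_cohort = cohort.subset(common)
    scores = score_signature(matrix, sig)
    pos = {s: i for i, s in enumerate(scores.sample_ids)}
    idx = [pos[s] for s in common]
    from .scoring import ScoreVector

    labelled = dichotomize(ScoreVector(common, scores.score[idx]), "median")
    lab = labelled.label
    if lab.sum() == 0 or lab.sum() == lab.size:
        logger.warning("signature %r: degenerate dichotomization", sig.name)
        return float("nan"), 1.0
    t, e = sub_cohort.time, sub_cohort.event
    test = two_sample_test(t[lab == 1], e[lab == 1], t[lab == 0], e[lab == 0], test_method)
    try:
        cox = cox_univariate(t, e, lab)
        hr = cox.hr
    except ValueError:
        hr = float("nan")
    return hr, test.p


@dataclass
class NullRankResult:
    """Ranking of a real signature against its composition-matched null."""

    n_signatures: int
    real_hr: float
    real_p: float
    frac_significant: float
    frac_hr_gt1_significant: float
    real_rank: int | None  # among significant signatures by descending HR
    real_rank_all: int  # among all signatures by descending HR
    empirical_p: float
    table: pd.DataFrame  # per-signature name/hr/p/significant

    def summary(self) -> str:
        rank = str(self.real_rank) if self.real_rank is not None else "n/a (not significant)"
        return "\n".join(
            [
                "Composition-matched random-signature null",
                "=========================================",
                f"N random signatures     = {self.n_signatures}",
                f"real signature          : HR = {self.real_hr:.4f}, p = {self.real_p:.4g}",
                f"fraction significant    = {self.frac_significant:.4f}",
                f"fraction sig. & HR > 1  = {self.frac_hr_gt1_significant:.4f}",
                f"real rank (significant) = {rank}",
                f"real rank (all)         = {self.real_rank_all}",
                f"empirical p             = {self.empirical_p:.4g}",
            ]
        )


def null_rank(
    real_sig: SignedSignature,
    matrix: ExpressionMatrix,
    cohort: ClinicalCohort,
    n_signatures: int = 1000,
    alpha: float = 0.05,
    rng: np.random.Generator | int | None = None,
    test_method: str = "gehan_wilcoxon",
    exclude_real_genes: bool = True,
) -> NullRankResult:
    """Rank a real signature against N composition-matched random ones.

    The random universe is all matrix genes, excluding the real
    signature's genes by default (so random signatures never partially
    overlap the real one). ``empirical_p = (1 + #{random significant with
    HR >= real HR}) / (N + 1)`` — the add-one convention keeps it
    positive. Ranks are reported both among significant signatures and
    among all signatures, by descending HR.
    """
    if n_signatures < 1:
        raise ValueError("n_signatures must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    present = set(matrix.gene_ids)
    missing = real_sig.genes - present
    if missing:
        logger.warning("real signature: %d gene(s) absent from matrix", len(missing))
    universe = sorted(present - real_sig.genes) if exclude_real_genes else sorted(present)
    n_up = len(real_sig.up)
    n_down = len(real_sig.down)

    real_hr, real_p = evaluate_signature_prognosis(real_sig, matrix, cohort, test_method)
    rand_sigs = generate_random_signatures(universe, n_up, n_down, n_signatures, rng)
    rows = [{"name": real_sig.name, "hr": real_hr, "p": real_p, "kind": "real"}]
    for sig in rand_sigs:
        hr, p = evaluate_signature_prognosis(sig, matrix, cohort, test_method)
        rows.append({"name": sig.name, "hr": hr, "p": p, "kind": "random"})
    table = pd.DataFrame(rows)
    table["significant"] = (table["p"] < alpha) & np.isfinite(table["hr"])

    rand = table[table["kind"] == "random"]
    frac_sig = float(rand["significant"].mean())
    frac_hr = float((rand["significant"] & (rand["hr"] > 1)).mean())

    real_significant = bool(table.iloc[0]["significant"])
    n_beat = int((rand["significant"] & (rand["hr"] >= real_hr)).sum()) if np.isfinite(real_hr) else n_signatures
    empirical_p = (1 + n_beat) / (n_signatures + 1) if real_significant else 1.0

    rank_all = 1 + int((rand["hr"] > real_hr).sum()) if np.isfinite(real_hr) else n_signatures + 1
    if real_significant:
        sig_rand = rand[rand["significant"]]
        real_rank: int | None = 1 + int((sig_rand["hr"] > real_hr).sum())
    else:
        real_rank = None

    result = NullRankResult(
        n_signatures=n_signatures,
        real_hr=real_hr,
        real_p=real_p,
        frac_significant=frac_sig,
        frac_hr_gt1_significant=frac_hr,
        real_rank=real_rank,
        real_rank_all=rank_all,
        empirical_p=float(empirical_p),
        table=table,
    )
    logger.info(
        "null rank: %.1f%% of %d random signatures significant (%.1f%% with HR>1)",
        100 * frac_sig, n_signatures, 100 * frac_hr,
    )
    return result
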