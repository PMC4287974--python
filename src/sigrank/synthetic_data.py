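"""Seeded generators emulating the statistical structure of the study data.

Each generator is fully determined by its spec (including the seed) and
emits a "truth" sidecar sufficient for parameter-recovery tests:

* :func:`simulate_tumor_matrix` — a two-group log2 expression matrix with a
  small set of planted signed differentially expressed genes on a null
  background (the mouse-tumor two-group comparison).
* :func:`simulate_cohort` — an expression matrix plus survival cohort in
  which a latent binary class drives both signature-gene expression and an
  exponential event hazard with a planted hazard ratio, under independent
  exponential censoring.
* :func:`simulate_reference_cohort` — pathway scores for a mutant /
  wild-type labelled reference cohort with a planted separation.
* :func:`simulate_dose_response` — cell-line panels whose pathway activity
  and log10 IC50 are bivariate normal with a planted correlation; observed
  viabilities are 4PL curves plus Gaussian noise.
* :func:`simulate_limiting_dilution` — Bernoulli transplant outcomes under
  the single-hit Poisson model P(positive | dose d) = 1 - exp(-f d).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import ClinicalCohort, ExpressionMatrix, SignedSignature
from .drug_response import DoseResponsePanel, four_pl

__all__ = [
    "TumorSimSpec",
    "CohortSimSpec",
    "PanelSimSpec",
    "LDSimSpec",
    "simulate_tumor_matrix",
    "simulate_cohort",
    "simulate_reference_cohort",
    "simulate_dose_response",
    "simulate_limiting_dilution",
]


@dataclass
class TumorSimSpec:
    """Two-group tumor comparison with planted signed effects.

    Defaults mirror the study scale: a genome-wide background (10,000
    genes), 20 tumors per group, and a planted signature of 7 up- and 17
    down-regulated genes shifted by 2 log2 units (fourfold) against a
    per-gene Gaussian noise SD of 0.5.
    """

    n_genes: int = 10_000
    n_per_group: int = 20
    n_up_planted: int = 7
    n_down_planted: int = 17
    planted_effect: float = 2.0
    noise_sd: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_up_planted + self.n_down_planted > self.n_genes:
            raise ValueError("planted gene counts exceed n_genes")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_per_group < 2:
            raise ValueError("need >= 2 samples per group")


def simulate_tumor_matrix(spec: TumorSimSpec) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate the two-group tumor matrix; returns (matrix, truth table).

    Background genes share a per-gene baseline mean (N(7, 1), log2 scale)
    across both groups. The signature-bearing tumors carry the planted
    shifts: up genes +planted_effect, down genes -planted_effect. Group
    labels are "claudin_low" (signature-bearing) and "control"; since
    "claudin_low" sorts first, the default derivation convention
    log2FC = mean(A) - mean(B) gives planted up genes a positive fold
    change.
    """
    rng = np.random.default_rng(spec.rng_seed)
    g = spec.n_genes
    n = spec.n_per_group
    gene_ids = [f"gene{i:05d}" for i in range(g)]
    samples_cl = [f"T{i:02d}" for i in range(n)]
    samples_ctrl = [f"C{i:02d}" for i in range(n)]

    baseline = rng.normal(7.0, 1.0, size=g)
    mat = baseline[:, None] + rng.normal(0.0, spec.noise_sd, size=(g, 2 * n))

    planted = rng.choice(g, size=spec.n_up_planted + spec.n_down_planted, replace=False)
    up_idx = planted[: spec.n_up_planted]
    down_idx = planted[spec.n_up_planted :]
    # shift the claudin_low columns (the first n)
    mat[up_idx, :n] += spec.planted_effect
    mat[down_idx, :n] -= spec.planted_effect

    df = pd.DataFrame(mat, index=gene_ids, columns=samples_cl + samples_ctrl)
    labels = {s: "claudin_low" for s in samples_cl} | {s: "control" for s in samples_ctrl}
    truth = pd.DataFrame(
        {
            "gene": [gene_ids[i] for i in np.concatenate([up_idx, down_idx])],
            "direction": ["up"] * spec.n_up_planted + ["down"] * spec.n_down_planted,
            "effect_log2": [spec.planted_effect] * spec.n_up_planted
            + [-spec.planted_effect] * spec.n_down_planted,
        }
    )
    return ExpressionMatrix(df, labels), truth


@dataclass
class CohortSimSpec:
    """Patient cohort whose hazard depends on a latent signature class.

    ``true_hr`` defaults to the claudin-low stratification effect (2.24).
    Event times are exponential with rate baseline_hazard for the negative
    class and baseline_hazard * true_hr for the positive class; censoring
    is independent exponential. Units are months.
    """

    n_patients: int = 400
    signature: SignedSignature | None = None
    true_hr: float = 2.24
    baseline_hazard: float = 0.02
    censor_rate: float = 0.01
    loading: float = 1.0
    n_background_genes: int = 500
    noise_sd: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.true_hr <= 0:
            raise ValueError("true_hr must be positive")
        if self.baseline_hazard <= 0 or self.censor_rate <= 0:
            raise ValueError("rates must be positive")
        if self.n_patients < 4:
            raise ValueError("need >= 4 patients")


def _default_signature() -> SignedSignature:
    up = {f"sig_up{i}" for i in range(7)}
    down = {f"sig_dn{i}" for i in range(17)}
    return SignedSignature("planted", up, down)


def simulate_cohort(
    spec: CohortSimSpec,
) -> tuple[ExpressionMatrix, ClinicalCohort, pd.DataFrame]:
    """Simulate (expression, cohort, truth) with a planted hazard ratio.

    Latent classes are balanced (floor(n/2) positive). Signature up genes
    are mean-shifted by +loading and down genes by -loading in positive
    patients; background genes carry no class information. Event and
    censoring times are independent exponentials; time = min, event =
    indicator of the event coming first.
    """
    sig = spec.signature or _default_signature()
    if len(sig) == 0:
        raise ValueError("signature must be nonempty")
    rng = np.random.default_rng(spec.rng_seed)
    n = spec.n_patients
    n_pos = n // 2
    cls = np.zeros(n, dtype=int)
    cls[:n_pos] = 1
    rng.shuffle(cls)
    samples = [f"P{i:04d}" for i in range(n)]

    up = sorted(sig.up)
    down = sorted(sig.down)
    bg = [f"bg{i:05d}" for i in range(spec.n_background_genes)]
    genes = up + down + bg
    mat = rng.normal(0.0, spec.noise_sd, size=(len(genes), n))
    mat[: len(up), :] += spec.loading * cls[None, :]
    mat[len(up) : len(up) + len(down), :] -= spec.loading * cls[None, :]

    hazard = spec.baseline_hazard * spec.true_hr**cls
    t_event = rng.exponential(1.0 / hazard)
    t_cens = rng.exponential(1.0 / spec.censor_rate, size=n)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    matrix = ExpressionMatrix(pd.DataFrame(mat, index=genes, columns=samples))
    cohort = ClinicalCohort(samples, time, event, subtype=["claudin-low"] * n)
    truth = pd.DataFrame({"sample": samples, "latent_class": cls, "true_hr": spec.true_hr})
    return matrix, cohort, truth


def simulate_reference_cohort(
    n_mut: int = 50,
    n_wt: int = 150,
    separation: float = 1.0,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Pathway scores for a mutant / wild-type labelled reference cohort.

    Mutant scores ~ N(0, 1); wild-type scores ~ N(separation, 1), i.e.
    wild-type activity sits above mutant activity by ``separation`` on
    average (a functional pathway scores higher).
    """
    rng = np.random.default_rng(rng_seed)
    mut = rng.normal(0.0, 1.0, size=n_mut)
    wt = rng.normal(separation, 1.0, size=n_wt)
    return pd.DataFrame(
        {
            "sample": [f"M{i:03d}" for i in range(n_mut)] + [f"W{i:03d}" for i in range(n_wt)],
            "score": np.concatenate([mut, wt]),
            "status": ["mutant"] * n_mut + ["wild-type"] * n_wt,
        }
    )


@dataclass
class PanelSimSpec:
    """Cell-line drug panels with a planted activity-IC50 correlation.

    Defaults mirror the follow-up screen: 7 independent experiments of 6
    lines each; pathway activity and log10 IC50 bivariate normal with
    correlation -0.70; IC50 geometric mean anchored at 0.2 uM; viabilities
    on a unit 4PL (bottom 0, top 1, hill 1) with Gaussian noise, clipped to
    the assay range [-0.1, 1.2].
    """

    n_experiments: int = 7
    n_lines: int = 6
    true_corr: float = -0.70
    ic50_anchor: float = 0.2
    log10_ic50_sd: float = 0.5
    bottom: float = 0.0
    top: float = 1.0
    hill: float = 1.0
    viability_noise_sd: float = 0.05
    doses: tuple[float, ...] = tuple(np.geomspace(0.001, 10.0, 8))
    n_replicates: int = 1
    drug: str = "eEF2K-inhibitor"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not -1 <= self.true_corr <= 1:
            raise ValueError("true_corr must lie in [-1, 1]")
        d = np.asarray(self.doses, dtype=float)
        if np.any(d <= 0) or np.unique(d).size < 5:
            raise ValueError("doses must be positive with >= 5 distinct values")
        if self.ic50_anchor <= 0:
            raise ValueError("ic50_anchor must be positive")


def simulate_dose_response(
    spec: PanelSimSpec,
) -> tuple[DoseResponsePanel, pd.DataFrame, pd.DataFrame]:
    """Simulate (panel, activities, truth) for the IC50 meta-analysis chain.

    Per line, (activity, log10 IC50) are bivariate normal with correlation
    ``true_corr``; activity ~ N(0, 1), log10 IC50 ~ N(log10(anchor),
    log10_ic50_sd). Viabilities are the 4PL at the line's IC50 plus
    Gaussian noise, clipped to [-0.1, 1.2].
    """
    rng = np.random.default_rng(spec.rng_seed)
    doses = np.asarray(spec.doses, dtype=float)
    rows = []
    act_rows = []
    truth_rows = []
    cov = np.array(
        [
            [1.0, spec.true_corr * spec.log10_ic50_sd],
            [spec.true_corr * spec.log10_ic50_sd, spec.log10_ic50_sd**2],
        ]
    )
    mean = np.array([0.0, np.log10(spec.ic50_anchor)])
    for e in range(spec.n_experiments):
        draws = rng.multivariate_normal(mean, cov, size=spec.n_lines)
        for l in range(spec.n_lines):
            activity, log_ic50 = draws[l]
            ic50 = 10.0**log_ic50
            line = f"exp{e}_line{l}"
            act_rows.append({"experiment": f"exp{e}", "line": line, "activity": activity})
            truth_rows.append(
                {
                    "experiment": f"exp{e}",
                    "line": line,
                    "true_ic50": ic50,
                    "true_activity": activity,
                    "true_corr": spec.true_corr,
                }
            )
            clean = four_pl(doses, spec.bottom, spec.top, spec.hill, ic50)
            for rep in range(spec.n_replicates):
                noisy = clean + rng.normal(0.0, spec.viability_noise_sd, size=doses.size)
                noisy = np.clip(noisy, -0.1, 1.2)
                for dose, viab in zip(doses, noisy):
                    rows.append(
                        {
                            "experiment": f"exp{e}",
                            "line": line,
                            "drug": spec.drug,
                            "dose_uM": dose,
                            "viability": viab,
                            "replicate": rep,
                        }
                    )
    panel = DoseResponsePanel(pd.DataFrame(rows))
    return panel, pd.DataFrame(act_rows), pd.DataFrame(truth_rows)


@dataclass
class LDSimSpec:
    """Limiting-dilution transplant design with a planted TIC frequency.

    Defaults mirror the sorted-fraction assay: frequency 1/57 with doses of
    10/50/100/500 cells and 6 recipients per dose.
    """

    true_frequency: float = 1.0 / 57.0
    doses: tuple[int, ...] = (10, 50, 100, 500)
    n_recipients: int = 6
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.true_frequency < 1:
            raise ValueError("true_frequency must lie in (0, 1)")
        if any(d <= 0 or int(d) != d for d in self.doses):
            raise ValueError("doses must be positive integers")
        if self.n_recipients < 1:
            raise ValueError("n_recipients must be >= 1")


def simulate_limiting_dilution(spec: LDSimSpec) -> pd.DataFrame:
    """Simulate a limiting-dilution table under the single-hit model.

    Each recipient at dose d is positive with probability 1 - exp(-f d).
    Columns: dose, n_injected, n_positive.
    """
    rng = np.random.default_rng(spec.rng_seed)
    rows = []
    for d in spec.doses:
        p = 1.0 - np.exp(-spec.true_frequency * d)
        k = int(rng.binomial(spec.n_recipients, p))
        rows.append({"dose": int(d), "n_injected": spec.n_recipients, "n_positive": k})
    return pd.DataFrame(rows)
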