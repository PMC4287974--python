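"""Domain containers and on-disk formats.

Every matrix is held as a pandas DataFrame with genes in rows and samples in
columns; values are log2-scale expression and are never re-logged by any
stage of the pipeline. Signatures travel as a signed GMT dialect in which a
pair of sets ``NAME_UP`` / ``NAME_DN`` is merged into a single
:class:`SignedSignature`. Clinical tables are plain TSV with columns
``sample``, ``time`` (months), ``event`` (1 = observed, 0 = censored) and
``subtype``.

Parsers validate and reject; they never silently coerce.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("sigrank")

__all__ = [
    "ExpressionMatrix",
    "SignedSignature",
    "ClinicalCohort",
    "RunConfig",
    "FormatError",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_gmt_signed",
    "write_gmt_signed",
    "read_clinical_tsv",
    "write_clinical_tsv",
    "load_config",
    "save_config",
]


class FormatError(ValueError):
    """An on-disk file violates the format contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Log2 expression values, genes x samples, with optional group labels.

    Parameters
    ----------
    values : pandas.DataFrame
        Genes in rows (index = gene ids), samples in columns. All entries
        must be finite; missing values are rejected, not imputed.
    group_labels : dict, optional
        Map sample id -> group name for two-group comparisons.
    """

    values: pd.DataFrame
    group_labels: dict[str, str] | None = None

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dupes = idx[idx.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids: {dupes[:5]}")
        if cols.duplicated().any():
            dupes = cols[cols.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dupes[:5]}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("expression matrix contains non-numeric values")
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise FormatError(
                f"non-finite expression value at gene {idx[bad[0]]!r}, "
                f"sample {cols[bad[1]]!r}"
            )
        if self.group_labels is not None:
            unknown = set(self.group_labels) - set(cols)
            if unknown:
                raise FormatError(f"group labels for unknown samples: {sorted(unknown)[:5]}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def groups(self) -> dict[str, list[str]]:
        """Samples per group label (only labelled samples)."""
        if self.group_labels is None:
            return {}
        out: dict[str, list[str]] = {}
        for s in self.sample_ids:
            if s in self.group_labels:
                out.setdefault(self.group_labels[s], []).append(s)
        return out


@dataclass(frozen=True)
class SignedSignature:
    """A named gene signature split into up- and down-regulated sets."""

    name: str
    up: frozenset[str]
    down: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "up", frozenset(self.up))
        object.__setattr__(self, "down", frozenset(self.down))
        overlap = self.up & self.down
        if overlap:
            raise FormatError(
                f"signature {self.name!r}: genes in both up and down sets: "
                f"{sorted(overlap)[:5]}"
            )

    def __len__(self) -> int:
        return len(self.up) + len(self.down)

    @property
    def genes(self) -> frozenset[str]:
        return self.up | self.down

    def flipped(self) -> "SignedSignature":
        return SignedSignature(self.name, self.down, self.up)


@dataclass
class ClinicalCohort:
    """Per-patient follow-up: time in months, event flag, subtype label."""

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray
    subtype: list[str] | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids in clinical table")
        if len(self.time) != len(self.sample_ids) or len(self.event) != len(self.sample_ids):
            raise FormatError("clinical columns have mismatched lengths")
        if np.any(self.time < 0):
            raise FormatError("negative survival time")
        if not np.isin(self.event, [0, 1]).all():
            raise FormatError("event indicator must be 0 or 1")
        self.event = self.event.astype(int)
        if self.subtype is not None and len(self.subtype) != len(self.sample_ids):
            raise FormatError("subtype column has mismatched length")

    def __len__(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        d = {"sample": self.sample_ids, "time": self.time, "event": self.event}
        if self.subtype is not None:
            d["subtype"] = self.subtype
        return pd.DataFrame(d)

    def subset(self, sample_ids: list[str]) -> "ClinicalCohort":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return ClinicalCohort(
            sample_ids=list(sample_ids),
            time=self.time[idx],
            event=self.event[idx],
            subtype=[self.subtype[i] for i in idx] if self.subtype is not None else None,
        )


@dataclass
class RunConfig:
    """All tunable thresholds of the pipeline in one place.

    Defaults mirror the printed settings of the analysis the package
    implements: FDR q < 0.05, twofold change, alpha 0.05, 1000 random
    signatures, top-30% AKT cutoff, p53-mutant reference median 0.15,
    bottom-quartile Pten-low rule.
    """

    q_threshold: float = 0.05
    fc_threshold: float = 2.0
    alpha: float = 0.05
    n_random_signatures: int = 1000
    akt_high_quantile: float = 0.30
    p53_reference_value: float = 0.15
    pten_low_quantile: float = 0.25
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.q_threshold < 1):
            raise ValueError("q_threshold must be in (0,1)")
        if self.fc_threshold <= 0:
            raise ValueError("fc_threshold must be positive (linear fold change)")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0,1)")
        if self.n_random_signatures < 1:
            raise ValueError("n_random_signatures must be >= 1")
        for q in (self.akt_high_quantile, self.pten_low_quantile):
            if not (0 < q < 1):
                raise ValueError("quantiles must be in (0,1)")
        if int(self.rng_seed) != self.rng_seed:
            raise ValueError("rng_seed must be an integer")
        self.rng_seed = int(self.rng_seed)

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# expression TSV
# ---------------------------------------------------------------------------


def read_expression_tsv(
    path: str | Path,
    orientation: str = "genes_in_rows",
    group_labels: Mapping[str, str] | None = None,
) -> ExpressionMatrix:
    """Read a log2 expression TSV (first column ids, header = ids).

    ``orientation`` is ``"genes_in_rows"`` (default) or
    ``"samples_in_rows"``; the latter transposes on load.
    """
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise FormatError(
                f"non-numeric cell at row {row!r}, column {col!r} in {path}"
            )
    if orientation == "samples_in_rows":
        df = df.T
    mat = ExpressionMatrix(df, dict(group_labels) if group_labels else None)
    logger.info("read expression matrix %s: %d genes x %d samples", path, mat.n_genes, mat.n_samples)
    return mat


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# signed GMT
# ---------------------------------------------------------------------------

_UP_SUFFIX = "_up"
_DN_SUFFIX = "_dn"


def read_gmt_signed(path: str | Path) -> list[SignedSignature]:
    """Read a GMT file, merging ``NAME_UP`` / ``NAME_DN`` pairs.

    Pairing is by case-insensitive suffix. An unpaired set yields a
    signature with an empty complement side. A gene appearing in both sides
    of the same signature is a validation error.
    """
    raw: dict[str, dict[str, set[str]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
            set_name = parts[0]
            genes = {g for g in parts[2:] if g}
            lower = set_name.lower()
            if lower.endswith(_UP_SUFFIX):
                base, side = set_name[: -len(_UP_SUFFIX)], "up"
            elif lower.endswith(_DN_SUFFIX):
                base, side = set_name[: -len(_DN_SUFFIX)], "down"
            else:
                base, side = set_name, "up"
            if base not in raw:
                raw[base] = {"up": set(), "down": set()}
                order.append(base)
            raw[base][side] |= genes
    sigs = [SignedSignature(name, raw[name]["up"], raw[name]["down"]) for name in order]
    logger.info("read %d signed signature(s) from %s", len(sigs), path)
    return sigs


def write_gmt_signed(signatures: list[SignedSignature], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sig in signatures:
            if sig.up:
                fh.write("\t".join([f"{sig.name}_UP", "up-regulated", *sorted(sig.up)]) + "\n")
            if sig.down:
                fh.write("\t".join([f"{sig.name}_DN", "down-regulated", *sorted(sig.down)]) + "\n")


# ---------------------------------------------------------------------------
# clinical TSV
# ---------------------------------------------------------------------------


def read_clinical_tsv(path: str | Path) -> ClinicalCohort:
    """Read a clinical TSV (sample/time/event[/subtype]).

    Rows with missing time or event are excluded with a logged count;
    negative times are a validation error.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    required = {"sample", "time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"clinical table missing columns: {sorted(missing)}")
    n0 = len(df)
    df = df.dropna(subset=["time", "event"])
    if len(df) < n0:
        logger.warning("excluded %d clinical row(s) with missing time/event", n0 - len(df))
    subtype = df["subtype"].astype(str).tolist() if "subtype" in df.columns else None
    cohort = ClinicalCohort(
        sample_ids=df["sample"].tolist(),
        time=df["time"].to_numpy(dtype=float),
        event=df["event"].to_numpy(),
        subtype=subtype,
    )
    logger.info("read clinical cohort %s: %d patients, %d events", path, len(cohort), int(cohort.event.sum()))
    return cohort


def write_clinical_tsv(cohort: ClinicalCohort, path: str | Path) -> None:
    cohort.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------


def load_config(path: str | Path) -> RunConfig:
    """Load a flat YAML mapping onto :class:`RunConfig`; unknown keys error."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise FormatError("config file must hold a flat key-value mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise FormatError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
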