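"""Panel data containers, PHQ-9 scoring, and cohort descriptives.

The central container is :class:`PanelDataset`: a wide-format longitudinal
panel of depressive-symptom sum scores (PHQ-9, range 0-27) measured over
``T`` waves, together with baseline covariates and end-of-study binary
outcomes.  Missing wave scores are represented by an explicit boolean mask
(and NaN in the score matrix) — never by sentinel numerics, since 0 is a
meaningful score on this scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SEVERITY_BANDS",
    "COVARIATE_SCHEMA",
    "OUTCOME_COLUMNS",
    "PanelDataset",
    "ParseReport",
    "phq9_sum",
    "severity_band",
    "load_panel",
    "write_panel",
    "attention_filter",
    "wave_retention",
]

#: PHQ-9 severity bands (label, lower, upper).  The two clinically anchored
#: cutoffs are <5 (no depression) and >=10 (moderate); the remaining splits
#: follow the standard PHQ-9 convention (5/10/15/20).
SEVERITY_BANDS: tuple[tuple[str, int, int], ...] = (
    ("none", 0, 4),
    ("mild", 5, 9),
    ("moderate", 10, 14),
    ("moderately_severe", 15, 19),
    ("severe", 20, 27),
)

#: Covariate name -> (min_code, max_code).  Ordinal covariates are coded as
#: small integers; binaries as 0/1.
COVARIATE_SCHEMA: dict[str, tuple[int, int]] = {
    "age_band": (1, 4),
    "sex": (0, 1),
    "living_alone": (0, 1),
    "relationship": (0, 1),
    "education": (1, 4),
    "ethnic_minority": (0, 1),
    "binge_drinking": (0, 1),
    "info_seeking": (0, 7),
    "physical_activity": (0, 7),
    "psych_dx_baseline": (0, 1),
    "worry_job_economy": (0, 6),
}

OUTCOME_COLUMNS = ("treatment_seeking", "diagnosis_T9")


def phq9_sum(items) -> int:
    """Sum score of the nine PHQ-9 items.

    Parameters
    ----------
    items : sequence of 9 integers, each in {0, 1, 2, 3}

    Returns
    -------
    int in [0, 27]

    A missing or out-of-range item raises ``ValueError``: partially answered
    item sets are refused rather than imputed.
    """
    items = list(items)
    if len(items) != 9:
        raise ValueError(f"PHQ-9 requires exactly 9 items, got {len(items)}")
    for i, v in enumerate(items):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise ValueError(f"item {i + 1} is missing; incomplete item sets are not scored")
        if int(v) != v or not 0 <= int(v) <= 3:
            raise ValueError(f"item {i + 1} value {v!r} outside 0-3")
    return int(sum(int(v) for v in items))


def severity_band(score) -> str:
    """Map a PHQ-9 sum score to its severity band label."""
    if int(score) != score or not 0 <= score <= 27:
        raise ValueError(f"score {score!r} outside 0-27")
    for label, lo, hi in SEVERITY_BANDS:
        if lo <= score <= hi:
            return label
    raise AssertionError("unreachable: bands partition 0-27")


@dataclass
class PanelDataset:
    """Wide-format longitudinal panel.

    Attributes
    ----------
    subject_id : array of opaque string ids, length n
    y : (n, T) float array of wave sum scores; NaN where unobserved
    observed : (n, T) boolean mask, True where a score was recorded
    covariates : DataFrame (n rows) with the columns of COVARIATE_SCHEMA
    outcomes : DataFrame (n rows) with binary end-of-study outcomes
        (NaN where the outcome was not collected)
    wave_labels : ordered wave names, default T1..T9
    """

    subject_id: np.ndarray
    y: np.ndarray
    observed: np.ndarray
    covariates: pd.DataFrame
    outcomes: pd.DataFrame
    wave_labels: tuple[str, ...] = field(default=None)  # type: ignore[assignment]
    #: inclusive score bounds; None for continuous (unbounded) scores
    score_range: tuple[float, float] | None = (0, 27)

    def __post_init__(self):
        self.subject_id = np.asarray(self.subject_id, dtype=object)
        self.y = np.asarray(self.y, dtype=float)
        self.observed = np.asarray(self.observed, dtype=bool)
        if self.wave_labels is None:
            self.wave_labels = tuple(f"T{t + 1}" for t in range(self.y.shape[1]))
        else:
            self.wave_labels = tuple(self.wave_labels)
        self.validate()

    # -- container protocol ------------------------------------------------
    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def T(self) -> int:
        return self.y.shape[1]

    def __len__(self) -> int:
        return self.n

    def validate(self) -> None:
        n, T = self.y.shape
        if self.observed.shape != (n, T):
            raise ValueError("observed mask shape differs from score matrix shape")
        if len(self.subject_id) != n:
            raise ValueError("subject_id length differs from score matrix rows")
        if len(set(self.subject_id)) != n:
            raise ValueError("duplicate subject ids")
        if len(self.wave_labels) != T:
            raise ValueError("wave_labels length differs from wave count")
        obs = self.y[self.observed]
        if self.score_range is not None and obs.size:
            lo, hi = self.score_range
            if np.any(obs < lo) or np.any(obs > hi):
                raise ValueError(f"observed scores outside [{lo}, {hi}]")
        if np.any(np.isnan(self.y[self.observed])):
            raise ValueError("NaN score marked as observed")
        if np.any(~self.observed.any(axis=1)):
            bad = np.where(~self.observed.any(axis=1))[0]
            raise ValueError(f"subjects with no observed wave: rows {bad.tolist()}")
        for col, (lo, hi) in COVARIATE_SCHEMA.items():
            if col in self.covariates.columns:
                v = self.covariates[col].dropna()
                if len(v) and (v.min() < lo or v.max() > hi):
                    raise ValueError(f"covariate {col} outside [{lo}, {hi}]")

    def subset(self, idx) -> "PanelDataset":
        idx = np.asarray(idx)
        return PanelDataset(
            subject_id=self.subject_id[idx],
            y=self.y[idx],
            observed=self.observed[idx],
            covariates=self.covariates.iloc[idx].reset_index(drop=True),
            outcomes=self.outcomes.iloc[idx].reset_index(drop=True),
            wave_labels=self.wave_labels,
            score_range=self.score_range,
        )


@dataclass
class ParseReport:
    """Diagnostics from load_panel: rows read, kept, and per-row problems."""

    n_rows: int
    n_kept: int
    problems: list[str]
    notes: list[str] = field(default_factory=list)


def _wave_columns(wave_labels):
    return [f"y_{w}" for w in wave_labels]


def load_panel(path, T: int = 9, strict: bool = True, score_range="auto"):
    """Read a wide CSV panel into a validated :class:`PanelDataset`.

    Expected columns: ``id``, ``y_T1..y_T<T>``, the covariates of
    COVARIATE_SCHEMA (optional), and the outcome columns (optional).  Empty
    cells are missing.  Returns ``(dataset, report)``.  With ``strict=True``
    any invalid row raises; otherwise invalid rows are dropped and logged in
    the report.

    ``score_range`` is the inclusive score bound pair, ``None`` for
    unbounded continuous scores, or ``"auto"`` (default): integer-valued
    panels are validated against the PHQ-9 scale [0, 27], panels with
    fractional scores (e.g. continuous-scale simulations) are left
    unbounded, with the choice noted in the parse report.
    """
    df = pd.read_csv(path, dtype={"id": str})
    wave_labels = tuple(f"T{t + 1}" for t in range(T))
    ycols = _wave_columns(wave_labels)
    missing_cols = [c for c in ["id", *ycols] if c not in df.columns]
    if missing_cols:
        raise ValueError(f"missing required columns: {missing_cols}")

    problems: list[str] = []
    keep = np.ones(len(df), dtype=bool)
    y = df[ycols].to_numpy(dtype=float)
    observed = ~np.isnan(y)
    notes: list[str] = []
    if score_range == "auto":
        vals = y[observed]
        if vals.size and np.all(vals == np.round(vals)):
            score_range = (0, 27)
        else:
            score_range = None
            notes.append(
                "fractional scores detected; treating panel as "
                "continuous-scale (no range validation)"
            )
    for i in range(len(df)):
        row_problems = []
        for j, c in enumerate(ycols):
            v = y[i, j]
            if score_range is not None and not np.isnan(v):
                lo, hi = score_range
                if not lo <= v <= hi:
                    row_problems.append(
                        f"row {i + 2}: column {c} score {v} outside [{lo}, {hi}]"
                    )
        if not observed[i].any():
            row_problems.append(f"row {i + 2}: no observed waves")
        if row_problems:
            problems.extend(row_problems)
            keep[i] = False

    dup = df["id"].duplicated(keep=False)
    if dup.any():
        rows = (df.index[dup] + 2).tolist()
        msg = f"duplicate ids at rows {rows}"
        if strict:
            raise ValueError(msg)
        problems.append(msg)
        keep &= ~dup.to_numpy()

    if strict and problems:
        raise ValueError("; ".join(problems))

    sub = df.loc[keep].reset_index(drop=True)
    cov_cols = [c for c in COVARIATE_SCHEMA if c in df.columns]
    out_cols = [c for c in OUTCOME_COLUMNS if c in df.columns]
    ds = PanelDataset(
        subject_id=sub["id"].to_numpy(dtype=object),
        y=sub[ycols].to_numpy(dtype=float),
        observed=~sub[ycols].isna().to_numpy(),
        covariates=sub[cov_cols].copy() if cov_cols else pd.DataFrame(index=sub.index),
        outcomes=sub[out_cols].copy() if out_cols else pd.DataFrame(index=sub.index),
        wave_labels=wave_labels,
        score_range=score_range,
    )
    return ds, ParseReport(n_rows=len(df), n_kept=len(sub), problems=problems, notes=notes)


def write_panel(data: PanelDataset, path) -> None:
    """Write a PanelDataset as the wide CSV that load_panel reads back."""
    out = {"id": data.subject_id}
    for j, w in enumerate(data.wave_labels):
        col = data.y[:, j].copy()
        col[~data.observed[:, j]] = np.nan
        out[f"y_{w}"] = col
    df = pd.DataFrame(out)
    for c in data.covariates.columns:
        df[c] = data.covariates[c].to_numpy()
    for c in data.outcomes.columns:
        df[c] = data.outcomes[c].to_numpy()
    df.to_csv(path, index=False)


def attention_filter(responses):
    """Keep-mask for the survey attention check.

    The check instructs respondents to answer "A little" (code 2) on a
    1-5 scale; any other code fails.  Returns ``(keep_mask, pass_rate)``.
    """
    responses = np.asarray(responses)
    if responses.size and (responses.min() < 1 or responses.max() > 5):
        raise ValueError("attention-check codes must be in 1-5")
    keep = responses == 2
    rate = float(keep.mean()) if responses.size else float("nan")
    return keep, rate


def wave_retention(data: PanelDataset) -> pd.DataFrame:
    """Observed subject count per wave and fraction relative to wave 1."""
    counts = data.observed.sum(axis=0)
    return pd.DataFrame(
        {
            "wave": list(data.wave_labels),
            "count": counts.astype(int),
            "fraction": counts / counts[0],
        }
    )
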