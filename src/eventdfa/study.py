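"""End-to-end study pipeline and statistical comparisons.

Runs the full per-subject analysis on a conforming trial table — prune,
trial-domain DFA of Y(n), ensemble event-domain DFA of X(t), commission
rate — at the single-session and appended-sessions time scales, then
builds the study-level summary: medians with quartiles by condition,
Wilcoxon matched-pairs signed-rank tests of the low/high time-stress
contrast, and per-condition linear regressions of commission errors on
the scaling indices.

The public entry point is the statsmodels-style pair
:class:`StudyAnalysis` (model) / :class:`StudyResults` (results); the
individual operations are importable functions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .dfa import DFAConfig, EVENT_DFA_CONFIG, TRIAL_DFA_CONFIG, dfa
from .exceptions import (
    DegenerateTestError,
    InsufficientDataError,
    InvalidInputError,
    SingularFitError,
)
from .transform import ensemble_event_alpha
from .trials import (
    TrialSeries,
    commission_rate,
    concatenate_sessions,
    prune_reaction_times,
    read_trial_table,
    series_from_table,
)

__all__ = [
    "StudyConfig",
    "SubjectConditionRecord",
    "StudyTables",
    "run_condition_analysis",
    "wilcoxon_signed_rank",
    "ols_regression",
    "build_summary_tables",
    "StudyAnalysis",
    "StudyResults",
]

logger = logging.getLogger(__name__)

RECORD_COLUMNS = [
    "subject",
    "condition",
    "timescale",
    "session",
    "alpha_Y",
    "alpha_X_mean",
    "alpha_X_sd",
    "commission_rate",
    "n_trials_used",
]

_VARIABLES = ["commission_rate", "alpha_Y", "alpha_X_mean"]


@dataclass(frozen=True)
class StudyConfig:
    """Pipeline settings: pruning bounds, DFA grids, ensemble size."""

    prune_lo: float = 100.0
    prune_hi: float = 1500.0
    ensemble_size: int = 100
    trial_dfa: DFAConfig = TRIAL_DFA_CONFIG
    event_dfa: DFAConfig = EVENT_DFA_CONFIG
    min_trials: int = 64
    #: "subject": average session-level values within subject before the
    #: paired test (n = subjects); "session": pair subject-session
    #: observations (n = subjects x sessions).
    session_pairing: str = "subject"


@dataclass(frozen=True)
class SubjectConditionRecord:
    """Per subject x condition x timescale analysis outcome."""

    subject_id: str
    condition: str
    timescale: str
    alpha_Y: float
    alpha_X_mean: float
    alpha_X_sd: float
    commission_rate: float
    n_trials_used: int
    session: Optional[int] = None

    def __post_init__(self) -> None:
        if self.alpha_X_sd < 0:
            raise InvalidInputError("alpha_X_sd must be >= 0")
        if not 0.0 <= self.commission_rate <= 1.0:
            raise InvalidInputError("commission_rate must lie in [0, 1]")


def _analyze_series(
    series: TrialSeries, config: StudyConfig, rng: np.random.Generator
) -> Optional[SubjectConditionRecord]:
    """One series -> record, or None when too short after pruning."""
    comm = commission_rate(series)
    pruned, _ = prune_reaction_times(series, config.prune_lo, config.prune_hi)
    rts = pruned.reaction_times()
    if rts.size < config.min_trials:
        logger.warning(
            "excluding %s/%s/%s: %d trials after pruning (< %d)",
            series.subject_id, series.condition, series.session,
            rts.size, config.min_trials,
        )
        return None
    try:
        alpha_y = dfa(rts, config.trial_dfa).alpha
        ens = ensemble_event_alpha(
            rts,
            n_realizations=config.ensemble_size,
            dfa_config=config.event_dfa,
            rng=rng,
        )
    except InsufficientDataError as exc:
        logger.warning(
            "excluding %s/%s/%s: %s",
            series.subject_id, series.condition, series.session, exc,
        )
        return None
    timescale = "appended" if series.session == "appended" else "session"
    return SubjectConditionRecord(
        subject_id=series.subject_id,
        condition=series.condition,
        timescale=timescale,
        session=None if timescale == "appended" else int(series.session),
        alpha_Y=float(alpha_y),
        alpha_X_mean=ens.mean,
        alpha_X_sd=ens.sd,
        commission_rate=comm,
        n_trials_used=int(rts.size),
    )


def run_condition_analysis(
    trial_table: pd.DataFrame,
    config: StudyConfig = StudyConfig(),
    rng: Optional[np.random.Generator] = None,
) -> List[SubjectConditionRecord]:
    """Per subject x condition records at session and appended time scales."""
    if rng is None:
        rng = np.random.default_rng()
    by_subject_condition: dict = {}
    records: List[SubjectConditionRecord] = []
    for subj, cond, sess, series in series_from_table(trial_table):
        by_subject_condition.setdefault((subj, cond), []).append(series)
        rec = _analyze_series(series, config, rng)
        if rec is not None:
            records.append(rec)
    for (subj, cond), session_series in sorted(by_subject_condition.items()):
        if len(session_series) > 1:
            appended = concatenate_sessions(session_series)
        else:
            appended = session_series[0]
            appended = TrialSeries(
                subject_id=appended.subject_id,
                session="appended",
                condition=appended.condition,
                frame=appended.frame,
            )
        rec = _analyze_series(appended, config, rng)
        if rec is not None:
            records.append(rec)
    return records


def records_frame(records: Sequence[SubjectConditionRecord]) -> pd.DataFrame:
    rows = [
        {
            "subject": r.subject_id,
            "condition": r.condition,
            "timescale": r.timescale,
            "session": r.session,
            "alpha_Y": r.alpha_Y,
            "alpha_X_mean": r.alpha_X_mean,
            "alpha_X_sd": r.alpha_X_sd,
            "commission_rate": r.commission_rate,
            "n_trials_used": r.n_trials_used,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def wilcoxon_signed_rank(
    paired_low: Sequence[float], paired_high: Sequence[float]
) -> Tuple[float, float]:
    """Wilcoxon matched-pairs signed-rank test, normal approximation.

    Zero differences are dropped (Wilcoxon convention), tied absolute
    differences are mid-ranked, and the variance carries the tie
    correction; no continuity correction is applied.  Z is signed by the
    rank-sum direction (positive when the first sample tends larger) and
    the p value is two-sided.
    """
    x = np.asarray(paired_low, dtype=np.float64)
    y = np.asarray(paired_high, dtype=np.float64)
    if x.shape != y.shape:
        raise InvalidInputError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise DegenerateTestError("all paired differences are zero")
    if n < 5:
        raise DegenerateTestError(
            f"need >= 5 non-zero differences for the normal approximation, got {n}"
        )
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    # tie correction: subtract sum(t^3 - t)/48 over groups of tied |d|
    _, counts = np.unique(ranks, return_counts=True)
    var -= float(np.sum(counts**3 - counts)) / 48.0
    if var <= 0:
        raise DegenerateTestError("zero variance after tie correction")
    z = (w_plus - mu) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def ols_regression(
    alpha: Sequence[float], errors_of_commission: Sequence[float]
) -> pd.DataFrame:
    """Simple OLS of commission errors on a scaling index.

    Returns the reporting set as a two-row frame (Intercept, Slope) with
    columns Estimate, SE, t, p and the model's adjusted R^2.
    """
    x = np.asarray(alpha, dtype=np.float64)
    y = np.asarray(errors_of_commission, dtype=np.float64)
    if x.size != y.size:
        raise InvalidInputError("predictor and response must have equal length")
    if x.size < 3:
        raise InsufficientDataError("need >= 3 observations for OLS")
    if np.ptp(x) == 0:
        raise SingularFitError("constant predictor: slope undefined")
    model = sm.OLS(y, sm.add_constant(x))
    res = model.fit()
    return pd.DataFrame(
        {
            "coefficient": ["Intercept", "Slope"],
            "Estimate": res.params,
            "SE": res.bse,
            "t": res.tvalues,
            "p": res.pvalues,
            "adj_R2": [np.nan, res.rsquared_adj],
        }
    ).reset_index(drop=True)


@dataclass(frozen=True)
class StudyTables:
    """Study-level summary tables (medians, Wilcoxon, regressions)."""

    medians: pd.DataFrame
    wilcoxon: pd.DataFrame
    regressions: pd.DataFrame

    def summary(self) -> str:
        out = [
            "Median (q25 q75) by time-stress condition",
            "-" * 57,
            self.medians.to_string(index=False),
            "",
            "Wilcoxon matched-pairs signed-rank tests (low vs high)",
            "-" * 57,
            self.wilcoxon.to_string(index=False),
            "",
            "OLS: commission errors ~ scaling index",
            "-" * 57,
            self.regressions.to_string(index=False),
        ]
        return "\n".join(out)

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.medians.to_csv(out / "medians.csv", index=False)
        self.wilcoxon.to_csv(out / "wilcoxon.csv", index=False)
        self.regressions.to_csv(out / "regressions.csv", index=False)


def _subject_level(records: pd.DataFrame, pairing: str) -> pd.DataFrame:
    """Session-scale observations used for the paired analyses."""
    sess = records[records["timescale"] == "session"]
    if pairing == "session":
        df = sess.copy()
        df["unit"] = df["subject"] + ":" + df["session"].astype(int).astype(str)
        return df
    agg = (
        sess.groupby(["subject", "condition"], as_index=False)[_VARIABLES]
        .mean()
    )
    agg["unit"] = agg["subject"]
    return agg


def build_summary_tables(
    records: Sequence[SubjectConditionRecord] | pd.DataFrame,
    session_pairing: str = "subject",
) -> StudyTables:
    """Medians/quartiles, Wilcoxon contrasts and regressions per timescale."""
    df = records if isinstance(records, pd.DataFrame) else records_frame(records)
    if df.empty:
        raise InsufficientDataError("no records to summarize")

    blocks = {
        "sessions": _subject_level(df, session_pairing),
        "appended": df[df["timescale"] == "appended"].assign(
            unit=lambda d: d["subject"]
        ),
    }

    med_rows, wil_rows, reg_rows = [], [], []
    for timescale, block in blocks.items():
        if block.empty:
            continue
        for var in _VARIABLES:
            row = {"timescale": timescale, "variable": var}
            for cond in ("low", "high"):
                v = block.loc[block["condition"] == cond, var].to_numpy()
                if v.size:
                    row[f"{cond}_median"] = float(np.median(v))
                    row[f"{cond}_q25"] = float(np.quantile(v, 0.25))
                    row[f"{cond}_q75"] = float(np.quantile(v, 0.75))
            med_rows.append(row)

        wide = block.pivot_table(
            index="unit", columns="condition", values=_VARIABLES
        )
        paired = wide.dropna()
        n_dropped = len(wide) - len(paired)
        if n_dropped:
            logger.warning(
                "%s: dropping %d unpaired unit(s)", timescale, n_dropped
            )
        for var in _VARIABLES:
            try:
                z, p = wilcoxon_signed_rank(
                    paired[(var, "low")], paired[(var, "high")]
                )
                wil_rows.append(
                    {
                        "timescale": timescale,
                        "variable": var,
                        "Z": z,
                        "p": p,
                        "n_pairs": len(paired),
                    }
                )
            except DegenerateTestError as exc:
                logger.warning("%s/%s: %s", timescale, var, exc)

        for var in ("alpha_Y", "alpha_X_mean"):
            for cond in ("low", "high"):
                sub = block[block["condition"] == cond]
                if len(sub) < 3 or np.ptp(sub[var].to_numpy()) == 0:
                    continue
                tab = ols_regression(sub[var], sub["commission_rate"])
                tab.insert(0, "condition", cond)
                tab.insert(0, "predictor", var)
                tab.insert(0, "timescale", timescale)
                reg_rows.append(tab)

    medians = pd.DataFrame(med_rows)
    wilcoxon = pd.DataFrame(wil_rows)
    regressions = (
        pd.concat(reg_rows, ignore_index=True) if reg_rows else pd.DataFrame()
    )
    return StudyTables(medians=medians, wilcoxon=wilcoxon, regressions=regressions)


class StudyAnalysis:
    """Model object: a trial table plus a pipeline configuration.

    Examples
    --------
    >>> from eventdfa import StudyAnalysis, StudyConfig
    >>> model = StudyAnalysis.from_csv("trials.csv")     # doctest: +SKIP
    >>> results = model.fit(seed=42)                     # doctest: +SKIP
    >>> print(results.summary())                         # doctest: +SKIP
    """

    def __init__(
        self, trial_table: pd.DataFrame, config: StudyConfig = StudyConfig()
    ):
        self.trial_table = trial_table
        self.config = config

    @classmethod
    def from_csv(cls, path, config: StudyConfig = StudyConfig()):
        return cls(read_trial_table(path), config)

    def fit(
        self,
        seed: Optional[int] = None,
        rng: Optional[np.random.Generator] = None,
    ) -> "StudyResults":
        if rng is None:
            rng = np.random.default_rng(seed)
        records = run_condition_analysis(self.trial_table, self.config, rng)
        tables = build_summary_tables(records, self.config.session_pairing)
        return StudyResults(
            records=records_frame(records), tables=tables, config=self.config
        )


@dataclass(frozen=True)
class StudyResults:
    """Fitted study pipeline: per-subject records and summary tables."""

    records: pd.DataFrame
    tables: StudyTables
    config: StudyConfig = field(compare=False, default=StudyConfig())

    def summary(self) -> str:
        n_sub = self.records["subject"].nunique()
        head = [
            "Event-time DFA study pipeline",
            "=" * 57,
            f"subjects: {n_sub}   records: {len(self.records)}   "
            f"ensemble size: {self.config.ensemble_size}",
            "",
        ]
        return "\n".join(head) + self.tables.summary()

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(out / "records.csv", index=False)
        self.tables.save(out)
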