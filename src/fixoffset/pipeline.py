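"""End-to-end orchestration: cleaning, classification, metrics, reports.

``run_pipeline`` executes the five cleaning stages in their fixed order,
applies the inclusion rules (per-fixation and per-subject), fits the
mixture sampler to every included fixation, screens normality, computes
the four accuracy metrics and the drift statistic, and aggregates a
cohort summary in the segment-stratified report format (percent
unimodal / positive / strong / very strong by number of fixation
segments, 1..5 plus the total row).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import PipelineConfig
from .excess_mass import acr_test
from .metrics import accuracy_metrics, drift_r2
from .multimodal import NEG_INF_LOG_BF, PriorSpec, fit_rjmcmc
from .normality import is_normal, simulate_limits
from .preprocess import (
    clean_recording,
    mean_offset_curve,
    select_analysis_window,
    trial_offset_matrix,
    estimate_latency,
    apply_latency,
)

logger = logging.getLogger("fixoffset")

__all__ = ["run_pipeline", "CohortSummary", "histogram_report", "PipelineResult"]

_CLASS_COLUMNS = ["unimodal", "positive", "strong", "very_strong"]


@dataclass
class CohortSummary:
    """Evidence-class percentages stratified by number of fixation segments."""

    table: pd.DataFrame  # rows: n_segments 1..5 + "total"

    def validate(self) -> None:
        pct = self.table[[f"pct_{c}" for c in _CLASS_COLUMNS]].sum(axis=1)
        nonzero = self.table["n_fixations"] > 0
        if not np.allclose(pct[nonzero], 100.0, atol=0.1):
            raise AssertionError("evidence-class percentages must sum to 100")
        body = self.table.loc[self.table.index != "total", "n_fixations"].sum()
        if body != self.table.loc["total", "n_fixations"]:
            raise AssertionError("segment-row counts must sum to the total")


@dataclass
class PipelineResult:
    fixations: pd.DataFrame  # one row per fixation (all, with inclusion flags)
    summary: CohortSummary
    recordings: pd.DataFrame  # per-recording latency / FixVelT / window
    limits: object  # NormalityLimits used for the screen
    window: tuple
    failures: list = None  # (subject, session, error) for skipped recordings


def _summarize(fix: pd.DataFrame, max_segments: int = 5) -> CohortSummary:
    used = fix[fix["included"]]
    rows = []
    idx = []
    strata = [(s, used[used["n_segments"] == s]) for s in range(1, max_segments + 1)]
    strata.append(("total", used))
    for name, grp in strata:
        n = len(grp)
        row = {"n_fixations": n}
        for c in _CLASS_COLUMNS:
            row[f"pct_{c}"] = 100.0 * (grp["evidence"] == c).mean() if n else 0.0
        rows.append(row)
        idx.append(name)
    table = pd.DataFrame(rows, index=idx)
    summary = CohortSummary(table=table)
    summary.validate()
    return summary


def histogram_report(
    values,
    bins=50,
    infinity_policy: str = "sentinel",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Histogram counts with the report-time infinity replacements applied.

    Positive-infinite values are set to the highest finite value in the
    batch; negative-infinite values to log(0.003).  Returns
    (counts, bin_edges, replaced_values).
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if infinity_policy == "sentinel":
        finite = v[np.isfinite(v)]
        hi = finite.max() if finite.size else NEG_INF_LOG_BF
        v = np.where(np.isposinf(v), hi, v)
        v = np.where(np.isneginf(v), NEG_INF_LOG_BF, v)
    elif infinity_policy == "drop":
        v = v[np.isfinite(v)]
    else:
        raise ValueError(f"unknown infinity_policy {infinity_policy!r}")
    counts, edges = np.histogram(v, bins=bins)
    return counts, edges, v


def run_pipeline(config: PipelineConfig, recordings) -> PipelineResult:
    """Run the full analysis over an iterable of GazeRecording objects."""
    recordings = list(recordings)
    if not recordings:
        raise ValueError("at least one recording is required")

    window = tuple(config.window)
    if config.recompute_window:
        # cohort-level mean offset curve from latency-aligned recordings
        mats = []
        for rec in recordings:
            shift = estimate_latency(rec, config.max_shift)
            aligned = apply_latency(rec, shift)
            mats.append(trial_offset_matrix(aligned, config.trial_len))
        curve, n_used = mean_offset_curve(np.vstack(mats))
        window = select_analysis_window(curve, config.window_width)
        logger.info("analysis window recomputed: %s (%d fixations in curve)",
                    window, n_used)

    limits = simulate_limits(config.normality_n, config.normality_reps,
                             seed=config.seed)
    prior = PriorSpec(kmax=config.kmax)
    master = np.random.SeedSequence(config.seed)

    fix_rows = []
    rec_rows = []
    failures = []
    for rec_i, rec in enumerate(recordings):
        try:
            res = clean_recording(
                rec, window=window, max_shift=config.max_shift,
                trial_len=config.trial_len, sg_window_ms=config.sg_window_ms,
                sg_polyorder=config.sg_polyorder,
            )
        except ValueError as exc:
            # partial-cohort results are still produced; the failure is
            # recorded in the result's manifest
            logger.warning("recording %s s%d failed: %s",
                           rec.subject, rec.session, exc)
            failures.append((rec.subject, rec.session, str(exc)))
            master.spawn(1)  # keep downstream seeding aligned
            continue
        rec_rows.append({
            "subject": rec.subject, "session": rec.session,
            "latency": res.latency, "fixvelt": res.fixvelt,
            "window_start": window[0], "window_end": window[1],
            "n_trials": len(res.trials),
            "n_included": sum(t.included for t in res.trials),
            "n_anticipatory": len(res.as_log),
        })
        seeds = master.spawn(1)[0].generate_state(len(res.trials) * 2)
        for t_i, trial in enumerate(res.trials):
            row = {
                "subject": rec.subject, "session": rec.session,
                "trial": trial.trial_index, "n_valid": trial.n_valid,
                "n_nan_blocks": trial.n_nan_blocks,
                "n_segments": trial.n_segments, "included": trial.included,
                "log_bf": np.nan, "evidence": None, "k_modal": np.nan,
                "acr_p": np.nan, "classic": np.nan, "max_comp_mean": np.nan,
                "median_acc": np.nan, "mean_acc": np.nan, "normal": False,
                "drift_r2": np.nan,
            }
            if not trial.included:
                logger.info(
                    "excluded %s s%d trial %d: n_valid=%d, nan_blocks=%d",
                    rec.subject, rec.session, trial.trial_index,
                    trial.n_valid, trial.n_nan_blocks)
                fix_rows.append(row)
                continue
            fit_seed = int(seeds[2 * t_i] % (2**31))
            post = fit_rjmcmc(trial.offsets, prior, n_iter=config.n_iter,
                              burn_in=config.burn_in, seed=fit_seed)
            normal = is_normal(trial.offsets[np.isfinite(trial.offsets)], limits)
            acc = accuracy_metrics(trial, post, normal)
            drift = drift_r2(trial, fs=rec.fs, n_fft=config.fft_length,
                             required_len=config.window_width)
            row.update({
                "log_bf": post.log_bf, "evidence": post.evidence,
                "k_modal": post.k_modal, "classic": acc.classic,
                "max_comp_mean": acc.max_comp_mean,
                "median_acc": acc.median_acc, "mean_acc": acc.mean_acc,
                "normal": normal,
                "drift_r2": drift.r2 if drift is not None else np.nan,
            })
            if config.run_acr:
                acr_seed = int(seeds[2 * t_i + 1] % (2**31))
                _, row["acr_p"] = acr_test(trial.offsets, config.acr_n_boot,
                                           seed=acr_seed)
            fix_rows.append(row)

    if not fix_rows:
        raise ValueError(f"every recording failed: {failures}")
    fix = pd.DataFrame(fix_rows)
    # session-level rule: drop subjects with any session under the minimum
    # number of good-quality fixations
    good = (fix[fix["included"]]
            .groupby(["subject", "session"]).size())
    bad_subjects = set()
    for (subj, sess), rec_row in (
        fix.groupby(["subject", "session"]).size().items()
    ):
        if good.get((subj, sess), 0) < config.min_good_fixations:
            bad_subjects.add(subj)
    if bad_subjects:
        logger.info("subjects excluded by the per-session minimum: %s",
                    sorted(bad_subjects))
        fix.loc[fix["subject"].isin(bad_subjects), "included"] = False

    # report-time Bayes-factor sentinel replacement
    finite = fix.loc[np.isfinite(fix["log_bf"]), "log_bf"]
    hi = finite.max() if len(finite) else NEG_INF_LOG_BF
    fix["log_bf_report"] = fix["log_bf"].replace(
        {np.inf: hi, -np.inf: NEG_INF_LOG_BF})

    summary = _summarize(fix, max_segments=5)
    return PipelineResult(
        fixations=fix, summary=summary, recordings=pd.DataFrame(rec_rows),
        limits=limits, window=window, failures=failures,
    )
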