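"""High-level Model/Results interface for whole-cohort apnea screening.

:class:`ApneaScreeningModel` is built from a cohort of recordings with
reference event annotations; :meth:`~ApneaScreeningModel.fit` runs the full
training protocol — feature extraction, subject-wise k-fold training of the
chosen classifier, pooled out-of-fold ROC, Youden threshold selection — and
returns an :class:`ApneaScreeningResults` carrying the fitted folds, the
operating point, per-night summaries and agreement statistics, with a
``summary()`` table.

    >>> nights = simulate_cohort(10, seed=3)
    >>> model = ApneaScreeningModel.from_simulations(nights, hidden_dim=32)
    >>> res = model.fit()
    >>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import agreement
from .features import FeatureConfig, FeatureFrame, build_features
from .models import CrossValFit, TrainConfig, predict_night, train_model
from .postprocess import (
    QuietConfig,
    SleepSummary,
    ThresholdConfig,
    classify_severity,
    compute_ahi,
    estimate_sleep_time,
    filter_short_events,
    threshold_probabilities,
)
from .recording import EventIntervalSet, Recording, events_from_labels, label_samples
from .synth import SimulatedNight

__all__ = ["ApneaScreeningModel", "ApneaScreeningResults", "compare_candidates"]


class ApneaScreeningModel:
    """Cohort-level screening model (MLP-Mixer or BiLSTM back end).

    Parameters
    ----------
    recordings, events
        One :class:`Recording` and one reference :class:`EventIntervalSet`
        per subject-night; events define the per-sample training labels.
    model_kind
        ``"mixer"`` (default) or ``"bilstm"``.
    hidden_dim, model_kw
        Architecture width (128 in the published protocol) and extra
        architecture keywords (``n_blocks``, ``dropout``, ``n_layers``).
    """

    def __init__(
        self,
        recordings: list[Recording],
        events: list[EventIntervalSet],
        model_kind: str = "mixer",
        feature_config: FeatureConfig | None = None,
        train_config: TrainConfig | None = None,
        quiet_config: QuietConfig | None = None,
        hidden_dim: int = 128,
        tau: int = 50,
        reference_ahi: np.ndarray | None = None,
        **model_kw,
    ) -> None:
        if len(recordings) != len(events):
            raise ValueError("one event set per recording required")
        self.recordings = list(recordings)
        self.events = list(events)
        self.model_kind = model_kind
        self.feature_config = feature_config or FeatureConfig()
        self.train_config = train_config or TrainConfig()
        self.quiet_config = quiet_config or QuietConfig()
        self.hidden_dim = hidden_dim
        self.tau = tau
        self.model_kw = model_kw
        self.reference_ahi = (
            None if reference_ahi is None else np.asarray(reference_ahi, dtype=float)
        )

    @classmethod
    def from_simulations(cls, nights: list[SimulatedNight], **kw) -> "ApneaScreeningModel":
        """Build from simulated nights, taking truth events as reference."""
        return cls(
            recordings=[n.recording for n in nights],
            events=[n.truth_events for n in nights],
            reference_ahi=np.array([n.truth_sleep.ahi for n in nights]),
            **kw,
        )

    def fit(self) -> "ApneaScreeningResults":
        frames = [build_features(r, self.feature_config) for r in self.recordings]
        labels = [label_samples(r, ev) for r, ev in zip(self.recordings, self.events)]
        datasets = [(f.to_array(), l.astype(float)) for f, l in zip(frames, labels)]
        cv = train_model(
            self.model_kind, datasets, self.train_config,
            hidden_dim=self.hidden_dim, **self.model_kw,
        )
        pooled_labels = np.concatenate(labels)
        pooled_scores = np.concatenate(cv.oof_probs)
        roc = agreement.roc_and_auc(pooled_labels, pooled_scores)
        theta_p = agreement.youden_threshold(roc)
        return ApneaScreeningResults(
            model=self, cv=cv, frames=frames, labels=labels,
            roc=roc, theta_p=theta_p,
        )


@dataclass
class ApneaScreeningResults:
    """Fit artifacts plus prediction and agreement methods."""

    model: ApneaScreeningModel
    cv: CrossValFit
    frames: list[FeatureFrame]
    labels: list[np.ndarray]
    roc: agreement.RocCurve
    theta_p: float

    @property
    def auc(self) -> float:
        """Pooled out-of-fold AUC on the internal [0, 1] scale."""
        return self.roc.auc

    @property
    def threshold_config(self) -> ThresholdConfig:
        return ThresholdConfig(
            theta_p=self.theta_p, tau=self.model.tau,
            sample_rate=self.model.recordings[0].sample_rate,
        )

    # -- probability prediction --------------------------------------

    def _probabilities(self, frame: FeatureFrame, fold: int | None) -> np.ndarray:
        window = self.model.train_config.window
        if fold is not None:
            return predict_night(self.cv.folds[fold].model, frame, window=window)
        # unseen recording: average the fold models' probabilities
        probs = [predict_night(f.model, frame, window=window) for f in self.cv.folds]
        return np.mean(probs, axis=0)

    def _summarize(self, rec: Recording, frame: FeatureFrame,
                   fold: int | None) -> tuple[SleepSummary, EventIntervalSet]:
        probs = self._probabilities(frame, fold)
        summary = estimate_sleep_time(rec, frame.position_code, self.model.quiet_config)
        lab = threshold_probabilities(probs, self.theta_p)
        events = events_from_labels(lab, rec.sample_rate, t0=rec.t[0])
        sleep_lo = summary.sleep_latency * 60.0
        sleep_hi = (rec.duration_minutes - summary.morning_wake) * 60.0
        events = events.clip(sleep_lo, sleep_hi)
        events = filter_short_events(events, self.model.tau, rec.sample_rate)
        summary.n_events = len(events)
        summary.ahi = compute_ahi(len(events), summary.sleep_time)
        summary.severity = classify_severity(summary.ahi)
        return summary, events

    def predict(self, rec: Recording) -> tuple[SleepSummary, EventIntervalSet]:
        """Whole-night summary + predicted events for a new recording.

        If the recording was part of the training cohort its out-of-fold
        model is used (no within-night leakage); otherwise probabilities
        are averaged over the fold models.
        """
        for i, train_rec in enumerate(self.model.recordings):
            if train_rec is rec:
                return self._summarize(rec, self.frames[i], int(self.cv.fold_of[i]))
        frame = build_features(rec, self.model.feature_config)
        return self._summarize(rec, frame, None)

    def score_cohort(self) -> pd.DataFrame:
        """Out-of-fold night-level estimates for every training recording."""
        rows = []
        for i, rec in enumerate(self.model.recordings):
            summary, _ = self._summarize(rec, self.frames[i], int(self.cv.fold_of[i]))
            row = {"subject": rec.subject_id, "fold": int(self.cv.fold_of[i])}
            row.update(summary.to_dict())
            if self.model.reference_ahi is not None:
                row["reference_ahi"] = float(self.model.reference_ahi[i])
            rows.append(row)
        return pd.DataFrame(rows)

    # -- agreement statistics ----------------------------------------

    def agreement_report(self, cutoffs=(5.0, 15.0, 30.0)) -> dict:
        """Pearson r, Bland–Altman and diagnostics vs the reference AHI."""
        if self.model.reference_ahi is None:
            raise ValueError("no reference AHI attached to this cohort")
        scored = self.score_cohort()
        est = scored["ahi"].to_numpy()
        ref = scored["reference_ahi"].to_numpy()
        ba = agreement.bland_altman(est, ref)
        return {
            "pearson_r": agreement.pearson_r(ref, est),
            "bland_altman": ba,
            "diagnostics": {
                c: agreement.diagnostic_metrics(ref, est, c) for c in cutoffs
            },
        }

    def summary(self) -> str:
        tc = self.model.train_config
        lines = [
            "Apnea screening cross-validation results",
            "=" * 46,
            f"model:            {self.model.model_kind}",
            f"recordings:       {len(self.model.recordings)}",
            f"folds:            {tc.k_folds}",
            f"iterations/fold:  {tc.iterations}",
            f"hidden dim:       {self.model.hidden_dim}",
            f"pooled OOF AUC:   {100 * self.auc:.2f}",
            f"Youden theta_p:   {self.theta_p:.4f}",
            f"tau (samples):    {self.model.tau}",
        ]
        for k, fold in enumerate(self.cv.folds):
            lines.append(
                f"  fold {k}: final BCE {fold.losses[-1]:.4f} "
                f"(from {fold.losses[0]:.4f}), val recordings {fold.val_indices}"
            )
        return "\n".join(lines)


def compare_candidates(
    recordings: list[Recording],
    events: list[EventIntervalSet],
    kinds: tuple[str, ...] = ("mixer", "bilstm"),
    **kw,
) -> tuple[str, dict[str, ApneaScreeningResults]]:
    """Fit each candidate architecture and keep the higher pooled-OOF AUC.

    Returns ``(chosen_kind, {kind: results})``; mirrors the protocol of
    training both classifiers identically and selecting by validation AUC.
    """
    results: dict[str, ApneaScreeningResults] = {}
    for kind in kinds:
        results[kind] = ApneaScreeningModel(
            recordings, events, model_kind=kind, **kw
        ).fit()
    candidates = {
        kind: (np.concatenate(res.labels), np.concatenate(res.cv.oof_probs))
        for kind, res in results.items()
    }
    chosen, _ = agreement.select_model(candidates)
    return chosen, results
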