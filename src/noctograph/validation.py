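"""k-fold cross-validation of the bedtime-inference pipeline.

Labeled users (fingerprint + reported bedtime) are randomly split into k
near-equal partitions per seed. Each fold trains the unified model on the
aggregate bedtime-relative profile of the other partitions, builds the
template bank, estimates bedtimes for both training and hold-out users,
and scores agreement with the reports by circular correlation and
within-1h/2h counts. Running k folds over each of several seeds yields the
k*len(seeds) validation rows summarised by medians and IQRs; comparable
training and hold-out correlations argue against overfitting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .circstats import accuracy_report
from .estimate import TemplateSet, estimate_bedtime, make_templates
from .fingerprint import CircadianFingerprint, aggregate_profiles, to_relative
from .model import FitError, UnifiedModel, fit_unified

__all__ = ["LabeledUser", "CVReport", "partition", "kfold_validate",
           "fit_final", "DEFAULT_SEEDS"]

#: Ten documented default seeds for the repeated cross-validation design.
DEFAULT_SEEDS = tuple(range(10))


@dataclass
class LabeledUser:
    author_id: str
    fingerprint: CircadianFingerprint
    reported_bedtime: int  # minutes after midnight, 15-min grid


@dataclass
class CVReport:
    """Per-run rows plus median/IQR summaries of the correlations."""

    runs: pd.DataFrame
    summaries: dict

    def save(self, path: Union[str, Path]) -> None:
        payload = {"runs": self.runs.to_dict(orient="records"),
                   "summaries": self.summaries}
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def partition(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Random split of range(n) into k near-equal disjoint partitions.

    Sizes differ by at most one; deterministic given the seed.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if n < k:
        raise ValueError("need at least k users to form k partitions")
    perm = np.random.default_rng(seed).permutation(n)
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    splits = np.split(perm, np.cumsum(sizes)[:-1])
    return [np.sort(s) for s in splits]


def _train_and_score(train: Sequence[LabeledUser],
                     holdout: Sequence[LabeledUser]):
    profiles = [to_relative(u.fingerprint, u.reported_bedtime) for u in train]
    model = fit_unified(aggregate_profiles(profiles))
    templates = make_templates(model)

    def score(users):
        pairs = []
        for u in users:
            est = estimate_bedtime(u.fingerprint, templates, u.author_id)
            if est.status == "ok":
                pairs.append((est.bedtime, u.reported_bedtime))
        return accuracy_report(pairs)

    return model, score(train), score(holdout)


def kfold_validate(
    users: Sequence[LabeledUser],
    k: int = 3,
    seeds: Sequence[int] = DEFAULT_SEEDS,
) -> CVReport:
    """Repeated k-fold cross-validation over the labeled cohort.

    Per seed, every user lands in exactly one hold-out partition; a run
    whose model fit fails is marked failed and the others proceed.
    """
    rows = []
    for seed in seeds:
        parts = partition(len(users), k, seed)
        for fold, hold_idx in enumerate(parts):
            hold_set = set(hold_idx.tolist())
            train = [u for i, u in enumerate(users) if i not in hold_set]
            hold = [users[i] for i in hold_idx]
            row = {"seed": seed, "fold": fold, "n_train": len(train),
                   "n_holdout": len(hold)}
            try:
                model, tr_rep, ho_rep = _train_and_score(train, hold)
            except FitError:
                row.update({"status": "failed", "train_corr": None,
                            "holdout_corr": None, "holdout_within_1h": None,
                            "holdout_within_2h": None})
            else:
                row.update({
                    "status": "ok",
                    "train_corr": tr_rep["circ_corr"],
                    "holdout_corr": ho_rep["circ_corr"],
                    "train_within_1h": tr_rep["within_1h"],
                    "train_within_2h": tr_rep["within_2h"],
                    "holdout_within_1h": ho_rep["within_1h"],
                    "holdout_within_2h": ho_rep["within_2h"],
                })
            rows.append(row)
    runs = pd.DataFrame(rows)
    ok = runs[runs["status"] == "ok"]
    summaries = {}
    for which in ("train_corr", "holdout_corr"):
        vals = ok[which].astype(float).dropna()
        summaries[which] = {
            "median": float(vals.median()) if len(vals) else None,
            "iqr": [float(vals.quantile(0.25)), float(vals.quantile(0.75))]
            if len(vals) else None,
        }
    return CVReport(runs=runs, summaries=summaries)


def fit_final(users: Sequence[LabeledUser]) -> UnifiedModel:
    """The released model: trained on all labeled users."""
    profiles = [to_relative(u.fingerprint, u.reported_bedtime) for u in users]
    return fit_unified(aggregate_profiles(profiles))


def fingerprint_matrix(users: Sequence[LabeledUser]) -> pd.DataFrame:
    """Export the 96-column fingerprint matrix (e.g. for external baselines)."""
    from .fingerprint import fingerprints_to_frame

    return fingerprints_to_frame({u.author_id: u.fingerprint for u in users})
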