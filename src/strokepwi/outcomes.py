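"""Outcome evaluation: mRS regrouping, mRSRF selection, the seven feature
groups and the held-out prediction report.

The 7-level 90-day modified Rankin Scale is evaluated at three
granularities: the identity 7-category (mRS_7), the 4-category
{0}, {1,2}, {3,4}, {5,6} (no symptoms / mild / moderate / severe, mRS_4),
and the 2-category {0-2} vs {3-6} (good vs poor outcome, mRS_2).

For each situation the best selection method picks the mRS radiomics
features (mRSRF) from the outstanding-feature pool against the situation's
labels; the survival feature (SurvF) is fit on the training portion of the
70/30 stratified split only (no outcome information leaks into the test
rows) and predicted for everyone.  The seven feature groups — CTI, mRSRF,
SurvF and their four fusions — are then scored with the ten classifier
families on the held-out 30%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.model_selection import train_test_split

from .benchmark import INDEX_NAMES, compute_indexes, model_registry
from .selection import FeatureSet, SelectorParams, select_features
from .significance import normalize_frame
from .survival import (SurvivalConfig, compute_survf, train_survival_net)

__all__ = [
    "SITUATIONS", "GROUP_NAMES", "regroup_mrs", "select_mrsrf",
    "assemble_feature_groups", "evaluate_outcomes", "PredictionReport",
]

log = logging.getLogger(__name__)

SITUATIONS = (2, 4, 7)
GROUP_NAMES = ("CTI", "mRSRF", "SurvF", "CTI+mRSRF", "CTI+SurvF",
               "mRSRF+SurvF", "ALL")

_MRS4_MAP = np.array([0, 1, 1, 2, 2, 3, 3])
_MRS2_MAP = np.array([0, 0, 0, 1, 1, 1, 1])


def regroup_mrs(mrs7, scheme: int = 7) -> np.ndarray:
    """Bucket 7-level mRS labels into the requested granularity."""
    mrs7 = np.asarray(mrs7, dtype=int)
    if mrs7.min() < 0 or mrs7.max() > 6:
        raise ValueError("mRS labels must lie in 0..6")
    if scheme == 7:
        return mrs7.copy()
    if scheme == 4:
        return _MRS4_MAP[mrs7]
    if scheme == 2:
        return _MRS2_MAP[mrs7]
    raise ValueError(f"unknown regrouping scheme {scheme}")


def select_mrsrf(outstanding: pd.DataFrame, labels, best_method: str,
                 params: SelectorParams | None = None) -> FeatureSet:
    """Apply the benchmark-winning method against the situation's labels.

    With Lasso (the typical winner) this keeps the features with nonzero
    L1-logistic coefficients, subject to the standard selection rule.  An
    empty selection is logged; downstream groups containing mRSRF are then
    degenerate but evaluation proceeds.  The two-class-only scorers (FS,
    TS) fall back to the good/poor dichotomy (label >= half the range) when
    handed a finer-grained situation.
    """
    labels = np.asarray(labels)
    if best_method in ("FS", "TS") and np.unique(labels).size > 2:
        log.info("%s requires two classes; scoring mRSRF against the "
                 "good/poor dichotomy", best_method)
        labels = (labels >= (labels.max() + 1) / 2).astype(int)
    fs = select_features(best_method, outstanding, labels, params)
    if not fs.features:
        log.warning("mRSRF selection by %s is empty", best_method)
    return fs


def encode_cti(cti: pd.DataFrame) -> pd.DataFrame:
    """Binary fields as 0/1, everything range-normalized (Eq. 1 style)."""
    return normalize_frame(cti.astype(float))


def assemble_feature_groups(cti: pd.DataFrame, mrsrf: pd.DataFrame,
                            survf: np.ndarray) -> dict:
    """The three single groups and four column-concatenated fusions; all
    columns range-normalized."""
    n = len(cti)
    if len(mrsrf) != n or len(survf) != n:
        raise ValueError("misaligned sample counts across feature blocks")
    cti_n = normalize_frame(cti.astype(float))
    mrsrf_n = (normalize_frame(mrsrf.astype(float))
               if mrsrf.shape[1] else mrsrf.astype(float))
    survf_df = normalize_frame(pd.DataFrame(
        {"SurvF": np.asarray(survf, dtype=float)}, index=cti.index))
    if mrsrf_n.shape[1] == 0:
        log.warning("mRSRF block is empty; mRSRF-containing groups are "
                    "degenerate")
    groups = {
        "CTI": cti_n,
        "mRSRF": mrsrf_n,
        "SurvF": survf_df,
        "CTI+mRSRF": pd.concat([cti_n, mrsrf_n], axis=1),
        "CTI+SurvF": pd.concat([cti_n, survf_df], axis=1),
        "mRSRF+SurvF": pd.concat([mrsrf_n, survf_df], axis=1),
        "ALL": pd.concat([cti_n, mrsrf_n, survf_df], axis=1),
    }
    return groups


@dataclass
class PredictionReport:
    """Per (situation, group, model) indexes and per-group model means."""

    cells: pd.DataFrame       # columns: situation, group, model, 5 indexes
    group_means: pd.DataFrame  # columns: situation, group, mAuc..mRecall

    def grid_complete(self, n_models: int = 10) -> bool:
        expected = len(SITUATIONS) * len(GROUP_NAMES) * n_models
        return len(self.cells) == expected


def evaluate_outcomes(cti: pd.DataFrame, outstanding: pd.DataFrame, mrs7,
                      best_method: str = "Lasso",
                      models: dict | None = None,
                      selector_params: SelectorParams | None = None,
                      survival_config: SurvivalConfig | None = None,
                      test_ratio: float = 0.3, seed: int = 0,
                      situations=SITUATIONS,
                      survf_fit: str = "train_only",
                      collect: dict | None = None) -> PredictionReport:
    """Full three-situation evaluation.

    Per situation: regroup the labels, select mRSRF, make one stratified
    70/30 split, fit SurvF on the training rows (``survf_fit='full'``
    reproduces the alternative whole-cohort fit), assemble the seven
    groups, fit every model on train and report the five indexes on test.
    """
    mrs7 = np.asarray(mrs7, dtype=int)
    if models is None:
        models = model_registry("paper", seed)
    survival_config = survival_config or SurvivalConfig(seed=seed)
    cells = []
    for scheme in situations:
        y = regroup_mrs(mrs7, scheme)
        counts = np.bincount(y)
        if (counts[counts > 0] < 2).any():
            raise ValueError(
                f"situation mRS_{scheme}: a class has a single sample; "
                "cannot stratify the 70/30 split")
        mrsrf_fs = select_mrsrf(outstanding, y, best_method, selector_params)
        mrsrf = outstanding[mrsrf_fs.features]

        idx = np.arange(len(y))
        tr, te = train_test_split(idx, test_size=test_ratio, stratify=y,
                                  random_state=seed)
        # survival fusion: age as event time, poor outcome as the event
        surv_in = pd.concat([encode_cti(cti), normalize_frame(mrsrf)
                             if mrsrf.shape[1] else mrsrf], axis=1)
        events = (mrs7 >= survival_config.event_threshold).astype(int)
        times = cti["age"].to_numpy(dtype=float)
        fit_rows = tr if survf_fit == "train_only" else idx
        net, _hist = train_survival_net(surv_in.iloc[fit_rows],
                                        times[fit_rows], events[fit_rows],
                                        survival_config)
        survf = compute_survf(net, surv_in)

        if collect is not None:
            collect[scheme] = {"survf": survf,
                               "mrsrf": list(mrsrf_fs.features)}
        groups = assemble_feature_groups(cti, mrsrf, survf)
        for gname in GROUP_NAMES:
            gdf = groups[gname]
            if gdf.shape[1] == 0:
                for mname in models:
                    cells.append({"situation": f"mRS_{scheme}",
                                  "group": gname, "model": mname,
                                  **{k: np.nan for k in INDEX_NAMES}})
                continue
            X = gdf.to_numpy(dtype=float)
            for mname, proto in models.items():
                m = clone(proto)
                m.fit(X[tr], y[tr])
                res = compute_indexes(m, X[te], y[te])
                cells.append({"situation": f"mRS_{scheme}", "group": gname,
                              "model": mname, **res})
    cells_df = pd.DataFrame(cells)
    means = (cells_df.groupby(["situation", "group"], sort=False)
             [list(INDEX_NAMES)].mean().reset_index())
    means = means.rename(columns={k: f"m{k}" for k in INDEX_NAMES})
    return PredictionReport(cells=cells_df, group_means=means)
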