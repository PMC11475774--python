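"""Ranked forward inclusion of regional features into a small classifier.

The composite ("meta-ROI") biomarker is built greedily: features are
ranked by their single-feature diagnostic accuracy (AUC), then added one
at a time as input nodes to a one-hidden-layer perceptron, and every
nested prefix is scored by repeated stratified hold-out AUC. Three
families are supported — cortical thickness only, regional volumes only,
and a hybrid that interleaves the two so each modality contributes its
best regions early.

The original analysis used a proprietary statistics package with
unreported network architecture and data partition; here the contract is
fixed and fully serialized instead: one hidden tanh layer, cross-entropy
loss with early stopping, z-scoring fit on the training split only, and a
repeated stratified 70/30 hold-out whose every split derives from the base
seed. Held-out AUC is therefore an honest out-of-sample estimate, not a
resubstitution figure.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .cohort import FeatureKey, FeatureTable
from .sdt import empirical_roc

__all__ = [
    "ClassifierSpec",
    "EvalProtocol",
    "RankedFeature",
    "EvalResult",
    "MetaRoiReport",
    "rank_features",
    "hybrid_order",
    "train_and_evaluate",
    "greedy_meta_roi",
    "feature_importance",
]

logger = logging.getLogger(__name__)

#: Regional-ROI candidates per family; global CSF composites (the total
#: ventricle volume) are not regional ROIs and are excluded from the
#: volumetric candidate set.
FAMILY_CANDIDATES: dict[str, tuple[tuple[str, str], ...]] = {
    "cortical": (
        ("entorhinal", "thickness"),
        ("middle-temporal", "thickness"),
        ("inferior-temporal", "thickness"),
        ("fusiform", "thickness"),
        ("temporal-pole", "thickness"),
        ("para-hippocampal", "thickness"),
        ("precuneus", "thickness"),
    ),
    "volumetric": (
        ("hippocampus", "volume"),
        ("inferior-lateral-ventricle", "volume"),
        ("amygdala", "volume"),
        ("entorhinal", "volume"),
        ("middle-temporal", "volume"),
        ("para-hippocampal", "volume"),
        ("precuneus", "volume"),
    ),
}


@dataclass(frozen=True)
class ClassifierSpec:
    """One-hidden-layer perceptron configuration.

    ``hidden_units=None`` sizes the layer as ``ceil((n_features + 2) / 2)``
    clamped to [2, 8] — small enough not to overfit a few hundred subjects.
    """

    hidden_units: int | None = None
    hidden_activation: Literal["tanh", "logistic"] = "tanh"
    max_epochs: int = 1000
    tol: float = 1e-4
    patience: int = 20
    standardize_inputs: bool = True

    def resolve_hidden(self, n_features: int) -> int:
        if self.hidden_units is not None:
            if self.hidden_units < 1:
                raise ValueError("hidden_units must be >= 1")
            return self.hidden_units
        return int(np.clip(math.ceil((n_features + 2) / 2), 2, 8))

    def to_dict(self) -> dict:
        return {
            "hidden_units": self.hidden_units,
            "hidden_activation": self.hidden_activation,
            "max_epochs": self.max_epochs,
            "tol": self.tol,
            "patience": self.patience,
            "standardize_inputs": self.standardize_inputs,
        }


@dataclass(frozen=True)
class EvalProtocol:
    """Repeated stratified hold-out evaluation.

    Repeat ``r`` uses seed ``base_seed + r`` for both the split and the
    network initialization, so the whole evaluation is reproducible from
    ``base_seed`` alone. Stratification is always on.
    """

    repeats: int = 25
    train_fraction: float = 0.70
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")

    def to_dict(self) -> dict:
        return {
            "repeats": self.repeats,
            "train_fraction": self.train_fraction,
            "stratified": True,
            "base_seed": self.base_seed,
        }


@dataclass(frozen=True)
class RankedFeature:
    """A feature with the single-feature AUC that earned its rank."""

    key: FeatureKey
    auc: float


@dataclass(frozen=True)
class EvalResult:
    mean_auc: float
    sd_auc: float
    per_repeat: tuple[float, ...]


@dataclass
class MetaRoiReport:
    """Greedy-inclusion report: one row per nested feature prefix.

    ``rows`` has columns n_features / features / mean_auc / sd_auc;
    ``best_features`` is the smallest prefix attaining the highest mean
    AUC; ``importance`` maps each best-set feature to its normalized
    permutation importance (max = 100).
    """

    family: str
    rows: pd.DataFrame
    best_features: list[FeatureKey]
    importance: dict[str, float]
    spec: ClassifierSpec
    protocol: EvalProtocol


def rank_features(
    det_table: pd.DataFrame,
    family: Literal["cortical", "volumetric"],
    *,
    pair: str = "NC_AD",
    candidates: Sequence[tuple[str, str]] | None = None,
) -> list[RankedFeature]:
    """Rank a family's candidate features by AUC, descending.

    ``det_table`` is a detectability report (columns region / measure /
    pair / auc). Candidates default to the family's regional-ROI set.
    Ties break alphabetically by region (logged).
    """
    if candidates is None:
        if family not in FAMILY_CANDIDATES:
            raise ValueError(f"unknown family {family!r}")
        candidates = FAMILY_CANDIDATES[family]
    sub = det_table[det_table["pair"] == pair]
    rows = []
    for region, measure in candidates:
        match = sub[(sub["region"] == region) & (sub["measure"] == measure)]
        if len(match):
            rows.append(RankedFeature(FeatureKey(region, measure), float(match["auc"].iloc[0])))
    if not rows:
        raise ValueError(f"no {family} candidates present in detectability table")
    aucs = [r.auc for r in rows]
    if len(set(aucs)) < len(aucs):
        logger.info("AUC ties in %s family broken alphabetically by region", family)
    return sorted(rows, key=lambda r: (-r.auc, r.key.region))


def hybrid_order(
    cortical_rank: Sequence[RankedFeature],
    volumetric_rank: Sequence[RankedFeature],
    mode: Literal["alternating", "global"] = "alternating",
    n_features: int = 5,
) -> list[RankedFeature]:
    """Merge the two family rankings into a hybrid inclusion order.

    The candidate pool is the global top-``n_features`` by AUC across both
    families. ``mode="alternating"`` then interleaves the families
    starting with the best cortical feature, so each modality contributes
    its strongest regions early; ``mode="global"`` orders the pool by
    strict descending AUC regardless of family. With one family empty the
    other's ranking is returned unchanged (truncated to the pool size).
    """
    pool = sorted(
        list(cortical_rank) + list(volumetric_rank),
        key=lambda r: (-r.auc, r.key.region),
    )[:n_features]
    if mode == "global":
        return pool
    cort = [r for r in cortical_rank if r in pool]
    vol = [r for r in volumetric_rank if r in pool]
    out: list[RankedFeature] = []
    turn = 0  # 0 = cortical
    while cort or vol:
        pick_from = cort if (turn == 0 and cort) or not vol else vol
        out.append(pick_from.pop(0))
        turn = 1 - turn
    return out


#: report abbreviations for the standard regions (M not MT, IV not ILV)
_REGION_CODES = {
    "entorhinal": "E",
    "middle-temporal": "M",
    "inferior-temporal": "I",
    "fusiform": "F",
    "temporal-pole": "T",
    "para-hippocampal": "PH",
    "precuneus": "P",
    "hippocampus": "H",
    "inferior-lateral-ventricle": "IV",
    "amygdala": "A",
    "total-ventricle": "TV",
}


def _feature_code(key: FeatureKey) -> str:
    """Short report code, e.g. entorhinal.thickness -> E-Thk."""
    code = _REGION_CODES.get(
        key.region, "".join(w[0].upper() for w in key.region.split("-"))
    )
    suffix = {"thickness": "Thk", "volume": "Vol", "surface": "Srf"}[key.measure]
    return f"{code}-{suffix}"


def _fit_once(x_train: np.ndarray, y_train: np.ndarray, spec: ClassifierSpec, seed: int):
    scaler = None
    if spec.standardize_inputs:
        scaler = StandardScaler().fit(x_train)
        x_train = scaler.transform(x_train)
    # early stopping on the training-loss plateau (tol over `patience`
    # epochs): a validation-score criterion is too noisy at these sample
    # sizes and can halt before the loss starts moving
    model = MLPClassifier(
        hidden_layer_sizes=(spec.resolve_hidden(x_train.shape[1]),),
        activation=spec.hidden_activation,
        max_iter=spec.max_epochs,
        tol=spec.tol,
        n_iter_no_change=spec.patience,
        learning_rate_init=0.01,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            model.fit(x_train, y_train)
        except ConvergenceWarning:
            logger.warning("classifier did not fully converge (seed %d); kept", seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                model.fit(x_train, y_train)
    return scaler, model


def _score_auc(scaler, model, x: np.ndarray, y: np.ndarray) -> float:
    if scaler is not None:
        x = scaler.transform(x)
    prob = model.predict_proba(x)[:, 1]
    return empirical_roc(prob, y).auc


def train_and_evaluate(
    table: FeatureTable,
    features: Sequence[FeatureKey],
    pair: tuple[str, str] = ("NC", "AD"),
    spec: ClassifierSpec = ClassifierSpec(),
    protocol: EvalProtocol = EvalProtocol(),
) -> EvalResult:
    """Held-out AUC of a feature set for one dichotomous contrast.

    Each repeat draws a fresh stratified train/test split, z-scores on the
    training split, trains the perceptron, and scores the empirical AUC of
    the predicted signal-class probability on the test split.
    """
    ref, sig = pair
    sub = table.subset([ref, sig])
    x, y = sub.xy(list(features), signal_group=sig)
    counts = np.bincount(y, minlength=2)
    if counts.min() < 10:
        raise ValueError(
            f"classes of pair {ref}->{sig} too small to split: {counts.tolist()}"
        )
    aucs = []
    for r in range(protocol.repeats):
        seed = protocol.base_seed + r
        x_tr, x_te, y_tr, y_te = train_test_split(
            x, y, train_size=protocol.train_fraction, stratify=y, random_state=seed
        )
        scaler, model = _fit_once(x_tr, y_tr, spec, seed)
        aucs.append(_score_auc(scaler, model, x_te, y_te))
    arr = np.asarray(aucs)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return EvalResult(float(arr.mean()), sd, tuple(arr.tolist()))


def feature_importance(
    scaler,
    model,
    x_test: np.ndarray,
    y_test: np.ndarray,
    features: Sequence[FeatureKey],
    n_permutations: int = 20,
    seed: int = 0,
) -> dict[str, float]:
    """Permutation importance on held-out data, rescaled so max = 100.

    Importance of a feature is the mean drop in test AUC over
    ``n_permutations`` independent shuffles of its column (negative drops
    floor at zero before normalization).
    """
    rng = np.random.default_rng(seed)
    base = _score_auc(scaler, model, x_test, y_test)
    drops = []
    for j in range(x_test.shape[1]):
        d = 0.0
        for _ in range(n_permutations):
            xp = x_test.copy()
            xp[:, j] = rng.permutation(xp[:, j])
            d += base - _score_auc(scaler, model, xp, y_test)
        drops.append(max(d / n_permutations, 0.0))
    top = max(drops)
    scale = 100.0 / top if top > 0 else 0.0
    return {f.column: d * scale for f, d in zip(features, drops)}


def greedy_meta_roi(
    table: FeatureTable,
    order: Sequence[RankedFeature | FeatureKey],
    spec: ClassifierSpec = ClassifierSpec(),
    protocol: EvalProtocol = EvalProtocol(),
    pair: tuple[str, str] = ("NC", "AD"),
    family: str = "custom",
) -> MetaRoiReport:
    """Score every nested prefix of an inclusion order; pick the best set.

    The best set is the highest mean hold-out AUC, ties resolved toward
    fewer features (adding regions beyond the informative core should not
    be rewarded). Permutation importances are computed for the best set on
    one final stratified split.
    """
    keys = [r.key if isinstance(r, RankedFeature) else r for r in order]
    if not keys:
        raise ValueError("inclusion order must be non-empty")
    rows = []
    results = []
    for k in range(1, len(keys) + 1):
        res = train_and_evaluate(table, keys[:k], pair, spec, protocol)
        results.append(res)
        rows.append(
            {
                "n_features": k,
                "features": " + ".join(_feature_code(f) for f in keys[:k]),
                "mean_auc": res.mean_auc,
                "sd_auc": res.sd_auc,
            }
        )
    best_k = int(np.argmax([round(r.mean_auc, 12) for r in results])) + 1
    best = keys[:best_k]
    # one final split for the importance chart
    ref, sig = pair
    sub = table.subset([ref, sig])
    x, y = sub.xy(best, signal_group=sig)
    x_tr, x_te, y_tr, y_te = train_test_split(
        x, y, train_size=protocol.train_fraction, stratify=y,
        random_state=protocol.base_seed,
    )
    scaler, model = _fit_once(x_tr, y_tr, spec, protocol.base_seed)
    imp = feature_importance(scaler, model, x_te, y_te, best, seed=protocol.base_seed)
    return MetaRoiReport(
        family=family,
        rows=pd.DataFrame(rows),
        best_features=best,
        importance=imp,
        spec=spec,
        protocol=protocol,
    )
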