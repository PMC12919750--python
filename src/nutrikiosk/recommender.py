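"""Plan-triage classifiers: the MLP recommendation engine and the fixed-rule
baseline it is compared against.

Feature encoding keeps the input dimension at exactly 15 (one value per coded
variable): continuous variables are standardized with training-set statistics;
categorical variables are mapped to fixed ordinal scores in [0, 1] (documented
in ``CATEGORY_MAPS``). Prediction ties break toward the more conservative
class (consultation over adjustment over adequate) — a safety-first rule for a
health device.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .cohort import (
    FEATURE_COLUMNS,
    LABELS,
    PREFERENCE,
    CohortRecord,
    split_train_test,
)
from .energy import ActivityLevel
from .mlp import MLPSpec, NeuralNet, TrainingHistory, train_network

__all__ = [
    "MLPSpec",
    "CATEGORY_MAPS",
    "CONTINUOUS_FEATURES",
    "EncoderStats",
    "TrainedModel",
    "encode_features",
    "train",
    "predict_class",
    "predict_batch",
    "fixed_rule_baseline",
    "save_model",
    "load_model",
]

CONTINUOUS_FEATURES = (
    "age_years", "height_m", "weight_kg", "bmi",
    "kcal_need", "cho_pct", "protein_pct", "fat_pct",
)

def _ordinal(values: Sequence[str]) -> dict[str, float]:
    n = len(values) - 1
    return {v: i / n for i, v in enumerate(values)}

#: Fixed ordinal codes in [0, 1] for the categorical variables. Clinically
#: graded variables use risk-spaced scores rather than equal spacing: the
#: concerning categories (poor control, insulin-dependent or labile glycemia,
#: low adherence, a diet dominated by fats or sweets) sit far from the benign
#: ones, mirroring their clinical distance.
CATEGORY_MAPS: dict[str, dict[str, float]] = {
    "sex": {"female": 0.0, "male": 1.0},
    "diabetes_type": {"type2": 0.0, "prediabetes": 0.8, "type1": 1.0},
    "glycemic_control": {"good": 0.0, "fair": 0.4, "poor": 1.0},
    "activity_level": _ordinal([a.value for a in ActivityLevel]),
    "dietary_adherence": {"low": 0.0, "medium": 0.6, "high": 1.0},
    "food_preference": _ordinal(PREFERENCE),
    "predominant_food_group": {
        "vegetable": 0.0, "legume": 0.05, "fruit": 0.1, "cereal_tuber": 0.15,
        "animal_protein": 0.2, "dairy": 0.3, "fats_oils": 0.8, "sugar_sweet": 1.0,
    },
}


@dataclass(frozen=True)
class EncoderStats:
    """Training-set standardization statistics for the continuous features."""

    mean: dict[str, float]
    sd: dict[str, float]  # zero-SD columns stored with a unit divisor


def _raw_value(rec: CohortRecord, name: str) -> float:
    value = getattr(rec, name)
    if name in CATEGORY_MAPS:
        try:
            return CATEGORY_MAPS[name][value]
        except KeyError:
            raise ValueError(f"unknown category {value!r} for variable {name!r}") from None
    return float(value)


def encode_features(
    records: Sequence[CohortRecord], fitted_stats: EncoderStats | None = None
) -> tuple[np.ndarray, EncoderStats]:
    """Encode records into the 15-column feature matrix.

    Without ``fitted_stats`` the standardization statistics are computed from
    the input (training mode); with them, they are applied unchanged
    (inference mode). Deterministic either way.
    """
    raw = np.array(
        [[_raw_value(rec, name) for name in FEATURE_COLUMNS] for rec in records],
        dtype=float,
    )
    cont_idx = [FEATURE_COLUMNS.index(c) for c in CONTINUOUS_FEATURES]
    if fitted_stats is None:
        mean = {c: float(raw[:, i].mean()) for c, i in zip(CONTINUOUS_FEATURES, cont_idx)}
        sd = {}
        for c, i in zip(CONTINUOUS_FEATURES, cont_idx):
            s = float(raw[:, i].std(ddof=0))
            sd[c] = s if s > 0 else 1.0  # constant column -> encoded as zeros
        fitted_stats = EncoderStats(mean=mean, sd=sd)
    X = raw.copy()
    for c, i in zip(CONTINUOUS_FEATURES, cont_idx):
        X[:, i] = (raw[:, i] - fitted_stats.mean[c]) / fitted_stats.sd[c]
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in encoded features")
    return X, fitted_stats


def _one_hot(labels: Sequence[str]) -> np.ndarray:
    idx = {lb: i for i, lb in enumerate(LABELS)}
    Y = np.zeros((len(labels), len(LABELS)))
    for r, lb in enumerate(labels):
        Y[r, idx[lb]] = 1.0
    return Y


@dataclass
class TrainedModel:
    spec: MLPSpec
    net: NeuralNet
    stats: EncoderStats
    history: TrainingHistory


def train(
    spec: MLPSpec,
    train_records: Sequence[CohortRecord],
    validation_fraction: float = 0.2,
) -> TrainedModel:
    """Fit the triage MLP on labeled cohort records.

    A label-stratified slice of ``validation_fraction`` is held out of the
    training records to drive early stopping.
    """
    if not train_records:
        raise ValueError("empty training set")
    present = {rec.label for rec in train_records}
    if present != set(LABELS):
        missing = sorted(set(LABELS) - present)
        raise ValueError(f"class(es) missing from training data: {', '.join(missing)}")
    fit_recs, val_recs = split_train_test(
        train_records, 1.0 - validation_fraction, seed=spec.seed
    )
    X_fit, stats = encode_features(fit_recs)
    X_val, _ = encode_features(val_recs, stats)
    net, history = train_network(
        spec, X_fit, _one_hot([r.label for r in fit_recs]),
        X_val, _one_hot([r.label for r in val_recs]),
    )
    return TrainedModel(spec=spec, net=net, stats=stats, history=history)


def _conservative_argmax(probs: np.ndarray) -> int:
    # LABELS is ordered least-to-most conservative, so the index doubles as
    # the conservatism rank used to break exact ties.
    return max(range(len(LABELS)), key=lambda i: (probs[i], i))


def predict_class(model: TrainedModel, record: CohortRecord) -> tuple[str, tuple[float, ...]]:
    """Triage label and softmax probability triple for one record."""
    X, _ = encode_features([record], model.stats)
    probs = model.net.predict_proba(X)[0]
    return LABELS[_conservative_argmax(probs)], tuple(float(p) for p in probs)


def predict_batch(model: TrainedModel, records: Sequence[CohortRecord]) -> list[str]:
    X, _ = encode_features(records, model.stats)
    probs = model.net.predict_proba(X)
    return [LABELS[_conservative_argmax(p)] for p in probs]


def fixed_rule_baseline(record: CohortRecord) -> str:
    """Coarse non-personalized rule used as the comparison engine: it sees
    only glycemic control and BMI."""
    if record.glycemic_control == "poor":
        return "REQUIRES_CONSULTATION"
    if record.glycemic_control == "fair" or not 18.5 <= record.bmi <= 30:
        return "MINOR_ADJUSTMENT"
    return "ADEQUATE"


# -- persistence (JSON weight store + CSV history) ----------------------------

def save_model(model: TrainedModel, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = {
        "spec": asdict(model.spec) | {"hidden_layers": list(model.spec.hidden_layers)},
        "encoder": {"mean": model.stats.mean, "sd": model.stats.sd},
        "weights": {
            "W": [w.tolist() for w in model.net.W],
            "b": [b.tolist() for b in model.net.b],
            "gamma": [g.tolist() for g in model.net.gamma],
            "beta": [b.tolist() for b in model.net.beta],
            "run_mean": [m.tolist() for m in model.net.run_mean],
            "run_var": [v.tolist() for v in model.net.run_var],
        },
    }
    (out / "model.json").write_text(json.dumps(payload), encoding="utf-8")
    hist = model.history
    lines = ["epoch,train_loss,train_acc,val_loss,val_acc"]
    for i in range(hist.epochs_run):
        lines.append(
            f"{i + 1},{hist.train_loss[i]:.6f},{hist.train_acc[i]:.6f},"
            f"{hist.val_loss[i]:.6f},{hist.val_acc[i]:.6f}"
        )
    (out / "history.csv").write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_model(model_dir: str | Path) -> TrainedModel:
    payload = json.loads((Path(model_dir) / "model.json").read_text(encoding="utf-8"))
    spec_raw = payload["spec"]
    spec_raw["hidden_layers"] = tuple(spec_raw["hidden_layers"])
    spec = MLPSpec(**spec_raw)
    net = NeuralNet(spec, np.random.default_rng(0))
    net.restore({k: [np.array(a) for a in v] for k, v in payload["weights"].items()})
    stats = EncoderStats(mean=payload["encoder"]["mean"], sd=payload["encoder"]["sd"])
    return TrainedModel(spec=spec, net=net, stats=stats, history=TrainingHistory())
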