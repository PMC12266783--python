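"""Epigenetic clocks: application, synthetic training, deceleration summaries.

A clock is a sparse linear predictor of age (weeks) from CpG beta values:
DNAmAGE_s = transform(intercept + sum_j w_j * beta_js). Probes missing
from a matrix (or missing in a single sample) are imputed with the
clock's gold-median reference values, mirroring how published mammalian
clocks are applied to arrays that only partially overlap their training
platform. Synthetic clocks are trained by ridge regression so the
end-to-end age-acceleration chain is testable without the proprietary
published coefficients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import BetaMatrix, ValidationError

log = logging.getLogger("methregen.clocks")

__all__ = [
    "ClockModel",
    "apply_clock",
    "train_synthetic_clock",
    "percent_deceleration",
    "read_clock",
    "write_clock",
]


@dataclass
class ClockModel:
    """Intercept + sparse probe weights + gold-median reference values."""

    name: str
    intercept: float
    weights: dict[str, float]
    gold_medians: dict[str, float]
    output_transform: str = "identity"
    transform_params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.output_transform not in ("identity", "log_linear"):
            raise ValidationError(f"unknown output_transform {self.output_transform!r}")
        missing = [p for p in self.weights if p not in self.gold_medians]
        if missing:
            raise ValidationError(f"clock probes without gold medians: {missing[:5]}")
        for p, m in self.gold_medians.items():
            if not (0.0 <= m <= 1.0):
                raise ValidationError(f"gold median for {p} outside [0, 1]: {m}")
        if not all(np.isfinite(list(self.weights.values()))):
            raise ValidationError("non-finite clock weight")

    def _transform(self, raw: np.ndarray) -> np.ndarray:
        if self.output_transform == "identity":
            return raw
        # log-linear calibration: age = exp(a * raw + b); slot for clocks
        # published with a log-scale linear predictor
        a = float(self.transform_params.get("a", 1.0))
        b = float(self.transform_params.get("b", 0.0))
        return np.exp(a * raw + b)


def apply_clock(beta: BetaMatrix, clock: ClockModel) -> pd.DataFrame:
    """DNAmAGE per sample with gold-median imputation of missing probes.

    Returns a DataFrame with columns sample_id, dnam_age, n_imputed.
    Raises if a weighted probe is absent from both the matrix and the
    gold-median reference (there would be nothing to impute from).
    """
    probes = list(clock.weights)
    if not probes:
        return pd.DataFrame(
            {
                "sample_id": list(beta.sample_ids),
                "dnam_age": clock._transform(np.full(len(beta.sample_ids), clock.intercept)),
                "n_imputed": 0,
            }
        )
    orphan = [p for p in probes if p not in clock.gold_medians and p not in set(beta.probe_ids)]
    if orphan:
        raise ValidationError(f"clock probes absent from matrix and gold medians: {orphan[:5]}")
    sub = beta.values.reindex(index=probes)
    medians = pd.Series({p: clock.gold_medians[p] for p in probes})
    imputed = sub.isna()
    filled = sub.apply(lambda col: col.fillna(medians))
    w = np.array([clock.weights[p] for p in probes])
    raw = clock.intercept + w @ filled.to_numpy(dtype=float)
    return pd.DataFrame(
        {
            "sample_id": list(beta.sample_ids),
            "dnam_age": clock._transform(raw),
            "n_imputed": imputed.sum(axis=0).to_numpy(dtype=int),
        }
    )


def train_synthetic_clock(
    beta: BetaMatrix,
    ages: pd.Series,
    penalty: float = 1.0,
    candidate_probes=None,
    name: str = "synthetic",
) -> ClockModel:
    """Ridge-penalized regression of age (weeks) on candidate-probe betas.

    Gold medians are the per-probe medians of the training matrix, so the
    trained clock can later be applied to matrices with missing probes.
    """
    from sklearn.linear_model import Ridge

    if penalty <= 0:
        raise ValidationError("penalty must be > 0")
    ages = ages.reindex(beta.sample_ids)
    if ages.isna().any():
        raise ValidationError("ages missing for some samples")
    if len(ages) < 2 or ages.nunique() < 2:
        raise ValidationError("need >=2 samples with >=2 distinct ages")
    probes = list(candidate_probes) if candidate_probes is not None else list(beta.probe_ids)
    X = beta.values.reindex(index=probes).to_numpy(dtype=float).T
    if np.isnan(X).any():
        med = np.nanmedian(X, axis=0)
        X = np.where(np.isnan(X), med, X)
    model = Ridge(alpha=penalty)
    model.fit(X, ages.to_numpy(dtype=float))
    weights = dict(zip(probes, model.coef_.astype(float)))
    medians = beta.values.reindex(index=probes).median(axis=1)
    return ClockModel(
        name=name,
        intercept=float(model.intercept_),
        weights=weights,
        gold_medians={p: float(medians[p]) for p in probes},
    )


@dataclass(frozen=True)
class Deceleration:
    percent: float
    weeks: float


def percent_deceleration(mean_control: float, mean_treated: float) -> Deceleration:
    """Percent DNAmAGE deceleration of a treated group versus its control.

    100 * (control - treated) / control, plus the absolute difference in
    weeks. Positive percent = deceleration (treated younger than control).
    """
    if mean_control <= 0:
        raise ValidationError("mean_control must be > 0")
    return Deceleration(
        percent=100.0 * (mean_control - mean_treated) / mean_control,
        weeks=mean_control - mean_treated,
    )


# ---------------------------------------------------------------------------
# Clock file TSV: '#key\tvalue' metadata lines, then probe/weight/gold rows
# ---------------------------------------------------------------------------


def write_clock(clock: ClockModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#name\t{clock.name}\n")
        fh.write(f"#intercept\t{float(clock.intercept)!r}\n")
        fh.write(f"#output_transform\t{clock.output_transform}\n")
        for k, v in clock.transform_params.items():
            fh.write(f"#transform_param\t{k}={float(v)!r}\n")
        fh.write("probe_id\tweight\tgold_median\n")
        probes = sorted(set(clock.weights) | set(clock.gold_medians))
        for p in probes:
            w = float(clock.weights.get(p, 0.0))
            fh.write(f"{p}\t{w!r}\t{float(clock.gold_medians[p])!r}\n")


def read_clock(path: str | Path) -> ClockModel:
    meta: dict[str, str] = {}
    tparams: dict[str, float] = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, val = line[1:].partition("\t")
                if key == "transform_param":
                    k, _, v = val.partition("=")
                    tparams[k] = float(v)
                else:
                    meta[key] = val
            elif line and not line.startswith("probe_id"):
                rows.append(line.split("\t"))
    if "intercept" not in meta:
        raise ValidationError("clock file missing #intercept metadata")
    weights = {p: float(w) for p, w, _ in rows if float(w) != 0.0}
    medians = {p: float(m) for p, _, m in rows}
    return ClockModel(
        name=meta.get("name", Path(path).stem),
        intercept=float(meta["intercept"]),
        weights=weights,
        gold_medians=medians,
        output_transform=meta.get("output_transform", "identity"),
        transform_params=tparams,
    )
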