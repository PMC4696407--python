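"""Radial-basis-function network cascade producing the P450 inhibition score.

The model is a ladder of small Gaussian RBF networks.  First, a 1-input,
11-hidden-unit, 1-output network is fitted per descriptor against the
normalized inhibited-isoform count, and descriptors whose network output
ranks compounds with Spearman rho > 0.4 are admitted.  The top descriptor's
network seeds the ladder; each subsequent rung is a 2-input network fusing
the current P450 inhibition score (PIS) with one more descriptor, and a rung
is kept only when it yields the maximum — and a strict — increase in
Spearman rho.  Construction stops when no candidate improves rho or every
admitted descriptor is used.

Each unit is trained on an internal 2:1:1 train/verification/testing split:
centers by k-means on the training subset, widths from nearest-center
distances, output weights by ridge least squares with the penalty picked on
the verification subset, and raw outputs min-max rescaled to [0,1] by the
training-output range so every PIS can feed the next rung.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .descriptor_space import (
    DescriptorMatrix,
    NormalizationParams,
    apply_normalization,
    fit_normalization,
)
from .validation_stats import holdout_split, spearman_rho

RHO_TOL = 1e-9


class CascadeError(RuntimeError):
    """Raised when cascade construction cannot proceed (e.g. empty screening)."""


@dataclass
class TrainConfig:
    """Knobs for unit training and cascade assembly."""

    hidden_units: int = 11
    screening_rho_threshold: float = 0.4
    split_ratio: tuple[int, int, int] = (2, 1, 1)
    restarts: int = 2
    ridge_grid: tuple[float, ...] = (1e-6, 1e-4, 1e-2, 1e-1, 1.0)
    seed: int = 0
    max_steps: int | None = None
    extension_pool: str = "admitted"  # or "all"

    def __post_init__(self) -> None:
        if not 0 <= self.screening_rho_threshold < 1:
            raise ValueError("screening threshold must be in [0, 1)")
        if any(r <= 0 for r in self.split_ratio):
            raise ValueError("split ratio parts must be positive")
        if self.extension_pool not in ("admitted", "all"):
            raise ValueError("extension_pool must be 'admitted' or 'all'")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["split_ratio"] = list(self.split_ratio)
        d["ridge_grid"] = list(self.ridge_grid)
        return d


@dataclass
class RbfUnit:
    """One trained Gaussian RBF network (1 or 2 inputs, 11 hidden, 1 output)."""

    centers: np.ndarray  # (k, d)
    widths: np.ndarray  # (k,)
    weights: np.ndarray  # (k + 1,), bias last
    out_min: float
    out_max: float
    train_r: float
    test_r: float
    ridge: float
    seed: int

    @property
    def input_dim(self) -> int:
        return self.centers.shape[1]

    def to_dict(self) -> dict:
        return {
            "centers": self.centers.tolist(),
            "widths": self.widths.tolist(),
            "weights": self.weights.tolist(),
            "out_min": self.out_min,
            "out_max": self.out_max,
            "train_r": self.train_r,
            "test_r": self.test_r,
            "ridge": self.ridge,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RbfUnit":
        return cls(
            centers=np.asarray(d["centers"], dtype=float),
            widths=np.asarray(d["widths"], dtype=float),
            weights=np.asarray(d["weights"], dtype=float),
            out_min=d["out_min"],
            out_max=d["out_max"],
            train_r=d["train_r"],
            test_r=d["test_r"],
            ridge=d["ridge"],
            seed=d["seed"],
        )


@dataclass
class LadderStep:
    descriptor_name: str
    unit: RbfUnit
    rho_after: float


@dataclass
class CascadeModel:
    """Ordered ladder of (descriptor, unit) rungs producing the PIS."""

    screening_table: list[tuple[str, float]]
    base_descriptor: str
    base_unit: RbfUnit
    steps: list[LadderStep]
    normalization: NormalizationParams
    config: TrainConfig
    final_rho: float
    input_hash: str = ""

    @property
    def descriptors(self) -> list[str]:
        return [self.base_descriptor] + [s.descriptor_name for s in self.steps]

    @property
    def rho_sequence(self) -> list[float]:
        base_rho = dict(self.screening_table)[self.base_descriptor]
        return [base_rho] + [s.rho_after for s in self.steps]

    def to_json(self) -> str:
        doc = {
            "format": "p450nnc-cascade/1",
            "config": self.config.to_dict(),
            "normalization": self.normalization.to_dict(),
            "screening_table": [[n, r] for n, r in self.screening_table],
            "base_descriptor": self.base_descriptor,
            "base_unit": self.base_unit.to_dict(),
            "steps": [
                {"descriptor": s.descriptor_name, "rho_after": s.rho_after, "unit": s.unit.to_dict()}
                for s in self.steps
            ],
            "final_rho": self.final_rho,
            "input_hash": self.input_hash,
        }
        return json.dumps(doc, sort_keys=True, indent=1)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "CascadeModel":
        doc = json.loads(text)
        cfg = doc["config"]
        cfg["split_ratio"] = tuple(cfg["split_ratio"])
        cfg["ridge_grid"] = tuple(cfg["ridge_grid"])
        return cls(
            screening_table=[(n, r) for n, r in doc["screening_table"]],
            base_descriptor=doc["base_descriptor"],
            base_unit=RbfUnit.from_dict(doc["base_unit"]),
            steps=[
                LadderStep(s["descriptor"], RbfUnit.from_dict(s["unit"]), s["rho_after"])
                for s in doc["steps"]
            ],
            normalization=NormalizationParams.from_dict(doc["normalization"]),
            config=TrainConfig(**cfg),
            final_rho=doc["final_rho"],
            input_hash=doc.get("input_hash", ""),
        )

    @classmethod
    def load(cls, path) -> "CascadeModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


def _derive_seed(base: int, *parts) -> int:
    h = zlib.crc32(repr(parts).encode()) & 0x7FFFFFFF
    return (base ^ h) % (2**31 - 1)


def _phi(x: np.ndarray, centers: np.ndarray, widths: np.ndarray) -> np.ndarray:
    d2 = cdist(x, centers, "sqeuclidean")
    return np.exp(-d2 / (2.0 * widths**2))


def _fit_rbf_core(x: np.ndarray, y: np.ndarray, config: TrainConfig, seed: int) -> RbfUnit:
    n = x.shape[0]
    k = config.hidden_units
    part = holdout_split(n, config.split_ratio, seed)
    tr, ve, te = part.group(0), part.group(1), part.group(2)

    km = KMeans(n_clusters=k, n_init=config.restarts, random_state=seed).fit(x[tr])
    centers = km.cluster_centers_
    dists = cdist(centers, centers)
    np.fill_diagonal(dists, np.inf)
    two_nearest = np.sort(dists, axis=1)[:, :2]
    widths = np.maximum(two_nearest.mean(axis=1), 1e-6)

    phi_tr = np.column_stack([_phi(x[tr], centers, widths), np.ones(tr.size)])
    phi_ve = np.column_stack([_phi(x[ve], centers, widths), np.ones(ve.size)])
    gram = phi_tr.T @ phi_tr
    rhs = phi_tr.T @ y[tr]
    penalty_mask = np.ones(k + 1)
    penalty_mask[-1] = 0.0  # bias unpenalized
    best = None
    for lam in config.ridge_grid:
        w = np.linalg.solve(gram + lam * np.diag(penalty_mask), rhs)
        mse = float(np.mean((phi_ve @ w - y[ve]) ** 2))
        if best is None or mse < best[0] - 1e-15:
            best = (mse, lam, w)
    _, lam, w = best

    raw_tr = phi_tr @ w
    out_min = float(raw_tr.min())
    out_max = float(raw_tr.max())
    if out_max - out_min < 1e-12:
        out_max = out_min + 1e-12

    unit = RbfUnit(centers, widths, w, out_min, out_max, 0.0, 0.0, float(lam), seed)
    pred_tr = predict_rbf(unit, x[tr])
    pred_te = predict_rbf(unit, x[te])
    unit.train_r = _safe_pearson(pred_tr, y[tr])
    unit.test_r = _safe_pearson(pred_te, y[te])
    return unit


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def fit_rbf(x, y, config: TrainConfig | None = None, seed: int | None = None) -> RbfUnit:
    """Fit one 1- or 2-input RBF unit mapping descriptors to the graded label.

    Requires at least four observations per hidden unit and a non-constant
    target; rows with missing inputs must be removed by the caller.
    """
    config = config or TrainConfig()
    seed = config.seed if seed is None else seed
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(y, dtype=float)
    if x.shape[1] not in (1, 2):
        raise ValueError("cascade units take 1 or 2 inputs")
    return _fit_rbf_any_dim(x, y, config, seed)


def _fit_rbf_any_dim(x: np.ndarray, y: np.ndarray, config: TrainConfig, seed: int) -> RbfUnit:
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values must be removed before fitting")
    if x.shape[0] < 4 * config.hidden_units:
        raise ValueError(
            f"need at least {4 * config.hidden_units} observations, got {x.shape[0]}"
        )
    if np.all(y == y[0]):
        raise ValueError("constant target")
    if np.all(x == x[0]):
        raise ValueError("constant (degenerate) input")
    return _fit_rbf_core(x, y, config, seed)


def fit_flat_rbf(x, y, config: TrainConfig | None = None, seed: int | None = None) -> RbfUnit:
    """Fit a single flat RBF network on all columns of x at once.

    The comparison baseline: same topology (11 Gaussian units, ridge readout,
    2:1:1 internal split) but one network over the whole admitted descriptor
    block instead of a ladder of 1- and 2-input units.
    """
    config = config or TrainConfig()
    seed = config.seed if seed is None else seed
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    return _fit_rbf_any_dim(x, np.asarray(y, dtype=float), config, seed)


def predict_rbf(unit: RbfUnit, x) -> np.ndarray:
    """Evaluate a unit: Gaussian basis + linear readout, rescaled to [0,1]."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[1] != unit.input_dim:
        raise ValueError(f"expected {unit.input_dim} inputs, got {x.shape[1]}")
    phi = np.column_stack([_phi(x, unit.centers, unit.widths), np.ones(x.shape[0])])
    raw = phi @ unit.weights
    return np.clip((raw - unit.out_min) / (unit.out_max - unit.out_min), 0.0, 1.0)


def screen_descriptors(
    matrix: DescriptorMatrix,
    labels: np.ndarray,
    config: TrainConfig | None = None,
) -> tuple[list[tuple[str, float]], dict[str, RbfUnit]]:
    """Fit a 1-input unit per descriptor and rank descriptors by Spearman rho.

    The rho is computed between each unit's PIS and the normalized labels
    over the whole modeling set.  Returns the table sorted by descending rho
    (ties by ascending name) and the fitted units.  Rows with a missing value
    for a descriptor are excluded from that descriptor's fit and rho.
    """
    config = config or TrainConfig()
    labels = np.asarray(labels, dtype=float)
    table: list[tuple[str, float]] = []
    units: dict[str, RbfUnit] = {}
    for name in matrix.names:
        col = matrix.column(name)
        ok = ~np.isnan(col)
        xs, ys = col[ok], labels[ok]
        try:
            unit = fit_rbf(xs, ys, config, _derive_seed(config.seed, "screen", name))
        except ValueError:
            continue  # constant or under-populated descriptor
        pis = predict_rbf(unit, xs)
        table.append((name, spearman_rho(pis, ys)))
        units[name] = unit
    table.sort(key=lambda t: (-round(t[1] / RHO_TOL), t[0]))
    return table, units


def extend_ladder(
    current_pis: np.ndarray,
    current_rho: float,
    candidates: Sequence[str],
    matrix: DescriptorMatrix,
    labels: np.ndarray,
    config: TrainConfig,
    step_index: int,
) -> LadderStep | None:
    """Try every candidate as the next rung; return the best strict improvement.

    Each candidate is fused with the current PIS in a 2-input unit; the
    candidate whose unit's PIS has maximal Spearman rho with the labels wins,
    provided that rho strictly exceeds the current rho (tolerance 1e-9).
    Rho ties resolve to the lexicographically first descriptor name.
    """
    best: LadderStep | None = None
    step_seed = _derive_seed(config.seed, "step", step_index)
    for name in sorted(candidates):
        col = matrix.column(name)
        x = np.column_stack([current_pis, col])
        unit = fit_rbf(x, labels, config, step_seed)
        rho = spearman_rho(predict_rbf(unit, x), labels)
        if best is None or rho > best.rho_after + RHO_TOL:
            best = LadderStep(name, unit, rho)
    if best is None or best.rho_after <= current_rho + RHO_TOL:
        return None
    return best


def build_cascade(
    matrix: DescriptorMatrix,
    labels: np.ndarray,
    config: TrainConfig | None = None,
) -> CascadeModel:
    """Fit normalization, screen descriptors, and assemble the ladder.

    ``matrix`` holds raw descriptor values; ``labels`` are inhibited-isoform
    counts normalized to [0,1].  The admitted descriptor block must be
    complete (no missing values) since every rung's PIS feeds the next.
    """
    config = config or TrainConfig()
    labels = np.asarray(labels, dtype=float)
    if len(matrix.ids) != labels.size:
        raise ValueError("matrix and labels are misaligned")
    norm = fit_normalization(matrix)
    nmat = apply_normalization(norm, matrix)

    table, units = screen_descriptors(nmat, labels, config)
    admitted = [n for n, r in table if r > config.screening_rho_threshold]
    if not admitted:
        raise CascadeError(
            f"no descriptor passed the rho > {config.screening_rho_threshold} screening"
        )
    pool = admitted if config.extension_pool == "admitted" else [n for n, _ in table]
    if np.isnan(nmat.frame[pool].to_numpy()).any():
        raise ValueError("admitted descriptors contain missing values")

    base = admitted[0]
    base_unit = units[base]
    current_pis = predict_rbf(base_unit, nmat.column(base))
    current_rho = dict(table)[base]

    remaining = [n for n in pool if n != base]
    steps: list[LadderStep] = []
    max_steps = config.max_steps if config.max_steps is not None else len(pool) - 1
    while remaining and len(steps) < max_steps:
        step = extend_ladder(
            current_pis, current_rho, remaining, nmat, labels, config, len(steps)
        )
        if step is None:
            break
        steps.append(step)
        remaining.remove(step.descriptor_name)
        x = np.column_stack([current_pis, nmat.column(step.descriptor_name)])
        current_pis = predict_rbf(step.unit, x)
        current_rho = step.rho_after

    digest = hashlib.sha256(
        np.ascontiguousarray(matrix.values).tobytes() + labels.tobytes()
    ).hexdigest()
    return CascadeModel(
        screening_table=table,
        base_descriptor=base,
        base_unit=base_unit,
        steps=steps,
        normalization=norm,
        config=config,
        final_rho=current_rho,
        input_hash=digest,
    )


def predict_pis(model: CascadeModel, matrix: DescriptorMatrix) -> np.ndarray:
    """P450 inhibition score in [0,1] for each compound in a raw matrix.

    Applies the stored normalization (with out-of-range clipping), evaluates
    the base unit, then each ladder rung in order.  Missing columns or values
    for required descriptors raise.
    """
    need = model.descriptors
    missing_cols = [n for n in need if n not in matrix.names]
    if missing_cols:
        raise KeyError(f"matrix lacks descriptors: {missing_cols}")
    sub = DescriptorMatrix(matrix.frame[need])
    if np.isnan(sub.values).any():
        raise ValueError("missing values for required descriptors")
    nmat = apply_normalization(model.normalization, sub)
    pis = predict_rbf(model.base_unit, nmat.column(model.base_descriptor))
    for step in model.steps:
        x = np.column_stack([pis, nmat.column(step.descriptor_name)])
        pis = predict_rbf(step.unit, x)
    return pis
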