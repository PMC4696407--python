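"""Synthetic benchmarks with planted structure for exercising the cascade.

The descriptor generator follows an ordinal latent-variable design: each
compound draws a latent inhibition propensity z ~ N(0,1); a handful of
informative descriptors are monotone transforms of z plus Gaussian noise,
the rest are pure noise; the inhibited-isoform count 0-5 is the number of
fixed cut points lying below z.  This mirrors the structure the cascade
assumes — a sparse set of descriptors monotonically linked to a graded
inhibition outcome — with signal strength as one knob (noise_sd).

A second generator produces toy assay tables (SMILES plus AC50 / activity
score values stratified across the decision regions) with planted truth, for
exercising the curation rules end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .descriptor_space import DescriptorMatrix, apply_normalization, normalize_label
from .rbf_cascade import (
    CascadeModel,
    TrainConfig,
    build_cascade,
    fit_flat_rbf,
    predict_pis,
    predict_rbf,
)
from .validation_stats import auroc, dichotomize, spearman_rho

LINK_SHAPES = ("linear", "sigmoid", "softplus")

#: default category proportions: each count 0..5 equally likely
DEFAULT_PROPORTIONS = (1 / 6,) * 6


@dataclass
class SyntheticSpec:
    """Parameters of the planted-descriptor generator.

    The defaults are the package's standard benchmark: 600 compounds,
    40 descriptors of which 5 carry signal, descriptor noise SD 0.5 on a
    unit-variance latent, equal count proportions.
    """

    n_compounds: int = 600
    n_descriptors: int = 40
    n_informative: int = 5
    links: tuple[str, ...] = ()
    noise_sd: float = 0.5
    thresholds: tuple[float, ...] | None = None
    proportions: tuple[float, ...] = DEFAULT_PROPORTIONS
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_informative > self.n_descriptors:
            raise ValueError("n_informative exceeds n_descriptors")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not self.links:
            self.links = tuple(LINK_SHAPES[i % len(LINK_SHAPES)] for i in range(self.n_informative))
        if len(self.links) != self.n_informative:
            raise ValueError("one link shape per informative descriptor")
        if any(l not in LINK_SHAPES for l in self.links):
            raise ValueError(f"links must be among {LINK_SHAPES}")
        if self.thresholds is None:
            cum = np.cumsum(self.proportions)[:-1]
            if not np.isclose(sum(self.proportions), 1.0):
                raise ValueError("proportions must sum to 1")
            self.thresholds = tuple(float(t) for t in norm.ppf(cum))
        if len(self.thresholds) != 5 or np.any(np.diff(self.thresholds) <= 0):
            raise ValueError("need 5 strictly increasing cut points")


@dataclass
class SyntheticDataset:
    """Generated matrix plus the planted ground truth."""

    matrix: DescriptorMatrix
    counts: np.ndarray
    latent: np.ndarray
    informative: list[str]
    spec: SyntheticSpec
    modeling_idx: np.ndarray = field(default=None)
    holdout_idx: np.ndarray = field(default=None)

    @property
    def labels(self) -> np.ndarray:
        return normalize_label(self.counts)


def _link(name: str, z: np.ndarray) -> np.ndarray:
    if name == "linear":
        return z
    if name == "sigmoid":
        return 1.0 / (1.0 + np.exp(-2.0 * z))
    if name == "softplus":
        return np.log1p(np.exp(z))
    raise ValueError(name)


def generate_qsar(spec: SyntheticSpec | None = None) -> SyntheticDataset:
    """Generate one planted-benchmark dataset, fully determined by the seed.

    Informative descriptor j is link_j(z) + N(0, noise_sd); the other
    descriptors are independent standard normals; count = number of cut
    points below z.  The dataset carries a seeded half/half modeling/holdout
    index split for recovery experiments.
    """
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(spec.seed)
    n, d, k = spec.n_compounds, spec.n_descriptors, spec.n_informative
    z = rng.standard_normal(n)
    names = [f"D{i + 1:03d}" for i in range(d)]
    informative_pos = sorted(rng.choice(d, size=k, replace=False).tolist())
    values = rng.standard_normal((n, d))
    for j, pos in enumerate(informative_pos):
        g = _link(spec.links[j], z)
        g = (g - g.mean()) / g.std()  # unit signal variance: noise_sd is SNR for every link
        values[:, pos] = g + rng.normal(0.0, spec.noise_sd, n)
    counts = np.searchsorted(np.asarray(spec.thresholds), z)
    ids = [f"C{i + 1:04d}" for i in range(n)]
    matrix = DescriptorMatrix.from_arrays(ids, names, values)
    perm = rng.permutation(n)
    half = n // 2
    return SyntheticDataset(
        matrix=matrix,
        counts=counts.astype(int),
        latent=z,
        informative=[names[p] for p in informative_pos],
        spec=spec,
        modeling_idx=np.sort(perm[:half]),
        holdout_idx=np.sort(perm[half:]),
    )


# small valid structures for assay-table fixtures; the last two plant a
# carbon-free structure and a >800 Da chain for the curation filters
_FIXTURE_SMILES = [
    "CC(=O)Oc1ccccc1C(=O)O",            # aspirin
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",       # caffeine
    "CCO.O",                             # ethanol hydrate
    "[Na+].CC(=O)[O-]",                  # sodium acetate
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",        # ibuprofen
    "c1ccccc1",                          # benzene
    "CC(N)Cc1ccccc1",                    # amphetamine
    "OC(=O)c1ccccc1O",                   # salicylic acid
    "O",                                 # water (inorganic plant)
    "C" * 60,                            # C60H122 chain, MW ~843 (weight plant)
]

_AC50_REGIONS = {
    "inhibitor": (0.1, 10.0),
    "indeterminate": (10.0 + 1e-6, 57.0),
    "non_inhibitor": (57.0 + 1e-6, 500.0),
}
_SCORE_REGIONS = {
    "inhibitor": (40.0 + 1e-6, 100.0),
    "indeterminate": (1e-6, 40.0),
    "non_inhibitor": (0.0, 0.0),
}


def generate_assay_table(n: int, seed: int = 0) -> pd.DataFrame:
    """Toy compound/evidence table spanning every call decision region.

    Each row carries one isoform's evidence (AC50 in uM or a PubChem-style
    activity score) plus the planted truth columns ``truth_call`` and
    ``measure_kind``.  The first six rows deterministically cover the six
    (measure, region) combinations so every decision region is represented.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    isoforms = ("CYP1A2", "CYP2C9", "CYP2C19", "CYP2D6", "CYP3A4")
    combos = [(kind, region) for kind in ("ac50_uM", "pubchem_activity_score")
              for region in ("inhibitor", "indeterminate", "non_inhibitor")]
    rows = []
    for i in range(n):
        kind, region = combos[i % 6] if i < 6 else combos[rng.integers(6)]
        regions = _AC50_REGIONS if kind == "ac50_uM" else _SCORE_REGIONS
        lo, hi = regions[region]
        value = float(lo if lo == hi else rng.uniform(lo, hi))
        rows.append(
            {
                "id": f"T{i + 1:03d}",
                "smiles": _FIXTURE_SMILES[i % len(_FIXTURE_SMILES)],
                "isoform": isoforms[i % 5],
                "measure_kind": kind,
                "value": value,
                "truth_call": region,
            }
        )
    return pd.DataFrame(rows)


def train_benchmark_cascade(
    dataset: SyntheticDataset, config: TrainConfig | None = None
) -> CascadeModel:
    """Build a cascade on the dataset's modeling half (seeded by the dataset)."""
    config = config or TrainConfig(seed=dataset.spec.seed)
    mod = dataset.modeling_idx
    mat = DescriptorMatrix(dataset.matrix.frame.iloc[mod])
    return build_cascade(mat, dataset.labels[mod], config)


def flat_baseline_holdout_rho(
    dataset: SyntheticDataset, model: CascadeModel
) -> float:
    """Holdout rho of a single flat RBF net on the model's admitted descriptors.

    The comparison baseline for the ladder: identical trainer and topology,
    one network over all admitted descriptors at once.
    """
    cfg = model.config
    admitted = [n for n, r in model.screening_table if r > cfg.screening_rho_threshold]
    mod, hold = dataset.modeling_idx, dataset.holdout_idx
    nmod = apply_normalization(
        model.normalization, DescriptorMatrix(dataset.matrix.frame.iloc[mod])
    )
    flat = fit_flat_rbf(
        nmod.frame[admitted].to_numpy(), dataset.labels[mod], cfg, cfg.seed + 104729
    )
    nhold = apply_normalization(
        model.normalization, DescriptorMatrix(dataset.matrix.frame.iloc[hold])
    )
    pis = predict_rbf(flat, nhold.frame[admitted].to_numpy())
    return spearman_rho(pis, dataset.counts[hold])


def cascade_vs_flat(seeds=range(1, 11)) -> dict:
    """Median holdout rho of the ladder vs the flat baseline over seeds."""
    cascade_rhos, flat_rhos = [], []
    for seed in seeds:
        ds = generate_qsar(SyntheticSpec(seed=seed))
        model = train_benchmark_cascade(ds)
        cascade_rhos.append(planted_recovery_report(ds, model).holdout_rho)
        flat_rhos.append(flat_baseline_holdout_rho(ds, model))
    return {
        "cascade_rhos": cascade_rhos,
        "flat_rhos": flat_rhos,
        "cascade_median": float(np.median(cascade_rhos)),
        "flat_median": float(np.median(flat_rhos)),
    }


@dataclass
class RecoveryReport:
    """How well a trained cascade recovers the planted structure."""

    informative_total: int
    informative_in_ladder: int
    ladder: list[str]
    holdout_rho: float
    holdout_auroc_multi: float | None

    @property
    def recovery_fraction(self) -> float:
        return self.informative_in_ladder / self.informative_total


def planted_recovery_report(dataset: SyntheticDataset, model: CascadeModel) -> RecoveryReport:
    """Evaluate a cascade (trained on the modeling half) on the holdout half.

    Reports the fraction of planted informative descriptors present in the
    ladder, the holdout Spearman rho between PIS and the count, and the
    holdout AUROC for separating multi-inhibitors (count >= 3) from the rest
    (None when the holdout has a single class).
    """
    hold = dataset.holdout_idx
    sub = DescriptorMatrix(dataset.matrix.frame.iloc[hold])
    pis = predict_pis(model, sub)
    counts = dataset.counts[hold]
    rho = spearman_rho(pis, counts)
    y = dichotomize(counts, "multi_task")
    auc = None
    if 0 < y.sum() < y.size:
        auc = auroc(pis, y, "multi_task").auroc
    in_ladder = set(model.descriptors)
    hits = sum(1 for name in dataset.informative if name in in_ladder)
    return RecoveryReport(
        informative_total=len(dataset.informative),
        informative_in_ladder=hits,
        ladder=model.descriptors,
        holdout_rho=float(rho),
        holdout_auroc_multi=auc,
    )
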