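"""Synthetic developmental expression data with planted module structure.

The generator emulates the shape of a bulk developmental-brain RNA-seq
resource: non-negative RPKM-scale values over samples spanning prenatal,
childhood and adulthood periods across several brain structures. Gene
profiles follow a one-factor model per module on the log2 scale,

    x_gs = baseline_g + loading_g * E_m(g)(s) + eps_gs,   eps ~ N(0, noise_sd),

where ``E_m`` is the module eigengene trajectory (unit variance across
samples). At least one module is prenatal-high (falling sigmoid over the
chronological axis) and one postnatal-high (rising sigmoid); remaining
trajectories are smooth random curves orthogonalised against the earlier
ones so that modules stay separable in an unsigned network. Log2 values are
mapped to RPKM by the exact inverse ``RPKM = 2**x - 1`` (floored at 0) so the
curation stage's transform round-trips.

A background of "noise" genes carries i.i.d. per-sample jitter with tiny
variance, giving the covariance-sum filter a true negative class. Gene-type
labels (protein-coding / antisense / lincRNA / other), ASD-risk labels
preferentially placed in designated modules, and planted hub lncRNAs with
high loadings in the ASD-dense module provide ground truth for the
enrichment and prioritisation stages.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .datasets import ConfigurationError, ExpressionMatrix

__all__ = ["SimConfig", "SimTruth", "generate_dataset", "write_dataset"]

_DEFAULT_STRUCTURES = (
    "neocortex",
    "hippocampus",
    "amygdala",
    "cerebellar_cortex",
)


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator.

    Defaults define the reference scenario used throughout the test suite:
    five planted modules of 100 genes, 50 low-covariance noise genes, 60
    samples split evenly over the three developmental periods, loadings in
    [0.8, 0.95] on a unit-variance eigengene, residual s.d. 0.3 on the log2
    scale, 15% lncRNAs, and 40 ASD-risk genes placed with 8-fold preference
    for the designated (prenatal-high) module.
    """

    n_modules: int = 5
    genes_per_module: int = 100
    n_noise_genes: int = 50
    n_samples: int = 60
    samples_per_period: dict = field(
        default_factory=lambda: {"prenatal": 20, "childhood": 20, "adulthood": 20}
    )
    structures: tuple = _DEFAULT_STRUCTURES
    loading_range: tuple = (0.8, 0.95)
    noise_sd: float = 0.3
    frac_lncRNA: float = 0.15
    n_asd_genes: int = 40
    asd_module_bias: float = 8.0
    seed: int = 0
    # extensions beyond the basic factor model
    lnc_module_bias: float = 3.0
    designated_modules: tuple = (1,)
    n_hub_lncrnas: int = 5
    hub_loading: float = 0.95
    noise_gene_sd: float = 0.05
    baseline_range: tuple = (2.0, 6.0)

    def validate(self) -> "SimConfig":
        def _positive(name):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")

        for name in ("n_modules", "genes_per_module", "n_samples", "n_asd_genes"):
            _positive(name)
        for name in ("n_noise_genes", "noise_sd", "noise_gene_sd", "n_hub_lncrnas"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        lo, hi = self.loading_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ConfigurationError("loading_range must lie within (0, 1]")
        if not 0.0 <= self.frac_lncRNA <= 1.0:
            raise ConfigurationError("frac_lncRNA must lie within [0, 1]")
        if self.asd_module_bias < 1.0:
            raise ConfigurationError("asd_module_bias must be >= 1")
        if self.lnc_module_bias < 1.0:
            raise ConfigurationError("lnc_module_bias must be >= 1")
        if set(self.samples_per_period) - {"prenatal", "childhood", "adulthood"}:
            raise ConfigurationError("samples_per_period has unknown period keys")
        if sum(self.samples_per_period.values()) != self.n_samples:
            raise ConfigurationError(
                "n_samples must equal the sum over samples_per_period"
            )
        bad = [m for m in self.designated_modules if not 1 <= m <= self.n_modules]
        if bad:
            raise ConfigurationError(f"designated_modules out of range: {bad}")
        if not 0.0 < self.hub_loading <= 1.0:
            raise ConfigurationError("hub_loading must lie within (0, 1]")
        return self

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("samples_per_period",):
            if key in raw and raw[key] is not None:
                raw[key] = dict(raw[key])
        for key in ("structures", "loading_range", "designated_modules", "baseline_range"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw).validate()


@dataclass
class SimTruth:
    """Ground truth: planted module labels (0 = noise gene), the eigengene
    trajectories used to build the data, and the planted hub lncRNAs."""

    true_module: pd.Series
    eigengene_profiles: pd.DataFrame
    planted_hub_lncRNAs: list


def _sample_metadata(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for period in ("prenatal", "childhood", "adulthood"):
        count = cfg.samples_per_period.get(period, 0)
        if period == "prenatal":
            ages = np.sort(rng.uniform(8.0, 37.0, size=count))
            unit = "pcw"
        elif period == "childhood":
            ages = np.sort(rng.uniform(4.0, 180.0, size=count))
            unit = "mos"
        else:
            ages = np.sort(rng.uniform(18.0, 40.0, size=count))
            unit = "yrs"
        for age in ages:
            rows.append({"age": round(float(age), 2), "age_unit": unit, "period": period})
    meta = pd.DataFrame(rows)
    meta["sample_id"] = [f"S{i + 1:03d}" for i in range(len(meta))]
    n_struct = len(cfg.structures)
    meta["structure"] = [cfg.structures[i % n_struct] for i in range(len(meta))]
    return meta[["sample_id", "structure", "age", "age_unit", "period"]]


def _sigmoid(t: np.ndarray, center: float, steep: float, rising: bool) -> np.ndarray:
    s = 1.0 / (1.0 + np.exp(-steep * (t - center)))
    return s if rising else 1.0 - s


def _standardize(v: np.ndarray) -> np.ndarray:
    v = v - v.mean()
    sd = v.std()
    if sd == 0:
        raise ConfigurationError("degenerate eigengene trajectory (zero variance)")
    return v / sd


def _eigengene_trajectories(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Module x sample trajectory matrix, each row standardised to unit s.d.

    Row 0 is prenatal-high (falling), row 1 postnatal-high (rising); later
    rows are random smooth curves residualised against all earlier rows.
    """
    n = cfg.n_samples
    t = np.linspace(0.0, 1.0, n)
    profiles = [_standardize(_sigmoid(t, 0.2, 20.0, rising=False))]

    def _orthogonal(raw: np.ndarray) -> np.ndarray | None:
        # project out earlier trajectories: modules stay separable in an
        # unsigned network and cross-module covariance sums vanish, so the
        # low-information screen sees every module symmetrically
        basis = np.vstack(profiles)
        raw = raw - raw.mean()
        resid = raw - basis.T @ np.linalg.lstsq(basis.T, raw, rcond=None)[0]
        return None if resid.std() < 1e-3 else _standardize(resid)

    if cfg.n_modules > 1:
        profiles.append(_orthogonal(_sigmoid(t, 0.8, 20.0, rising=True)))
    while len(profiles) < cfg.n_modules:
        coef = rng.normal(size=4)
        raw = sum(c * np.cos((k + 1) * np.pi * t) for k, c in enumerate(coef))
        resid = _orthogonal(raw)
        if resid is not None:
            profiles.append(resid)
    return np.vstack(profiles)


def _weighted_choice(rng, candidates, weights, size):
    w = np.asarray(weights, dtype=float)
    return rng.choice(candidates, size=size, replace=False, p=w / w.sum())


def generate_dataset(config: SimConfig):
    """Generate one synthetic dataset.

    Returns
    -------
    (ExpressionMatrix, pandas.DataFrame, pandas.DataFrame, SimTruth)
        RPKM-scale expression, sample metadata, gene annotation, and the
        planted ground truth. Deterministic given ``config.seed``.
    """
    cfg = config.validate()
    rng = np.random.default_rng(cfg.seed)

    meta = _sample_metadata(cfg, rng)
    sample_ids = list(meta["sample_id"])
    trajectories = _eigengene_trajectories(cfg, rng)

    n_module_genes = cfg.n_modules * cfg.genes_per_module
    n_genes = n_module_genes + cfg.n_noise_genes
    gene_ids = [f"G{i + 1:05d}" for i in range(n_genes)]
    true_module = np.zeros(n_genes, dtype=int)
    true_module[:n_module_genes] = np.repeat(
        np.arange(1, cfg.n_modules + 1), cfg.genes_per_module
    )

    lo, hi = cfg.loading_range
    loadings = rng.uniform(lo, hi, size=n_genes)
    baselines = rng.uniform(*cfg.baseline_range, size=n_genes)

    # hub lncRNAs: high-loading members of the first designated module
    anchor = cfg.designated_modules[0]
    anchor_idx = np.flatnonzero(true_module == anchor)
    n_hubs = min(cfg.n_hub_lncrnas, len(anchor_idx))
    hub_idx = rng.choice(anchor_idx, size=n_hubs, replace=False)
    loadings[hub_idx] = cfg.hub_loading

    log2 = np.empty((n_genes, cfg.n_samples))
    for g in range(n_genes):
        m = true_module[g]
        if m == 0:
            log2[g] = baselines[g] + rng.normal(0.0, cfg.noise_gene_sd, cfg.n_samples)
        else:
            signal = loadings[g] * trajectories[m - 1]
            log2[g] = baselines[g] + signal + rng.normal(0.0, cfg.noise_sd, cfg.n_samples)

    rpkm = np.clip(np.exp2(log2) - 1.0, 0.0, None)
    expr = ExpressionMatrix(
        pd.DataFrame(rpkm, index=gene_ids, columns=sample_ids), scale="rpkm"
    )

    # gene-type labels: lncRNAs placed with mild preference for designated
    # modules, hubs always lncRNA; ASD labels drawn from the non-lncRNA pool
    # with strong preference for designated modules.
    is_lnc = np.zeros(n_genes, dtype=bool)
    is_lnc[hub_idx] = True
    n_lnc_target = int(round(cfg.frac_lncRNA * n_genes))
    remaining = max(n_lnc_target - n_hubs, 0)
    pool = np.flatnonzero(~is_lnc)
    if remaining and len(pool):
        w = np.where(np.isin(true_module[pool], cfg.designated_modules),
                     cfg.lnc_module_bias, 1.0)
        chosen = _weighted_choice(rng, pool, w, min(remaining, len(pool)))
        is_lnc[chosen] = True

    is_asd = np.zeros(n_genes, dtype=bool)
    asd_pool = np.flatnonzero(~is_lnc)
    if cfg.n_asd_genes > len(asd_pool):
        raise ConfigurationError("n_asd_genes exceeds the non-lncRNA gene count")
    w = np.where(np.isin(true_module[asd_pool], cfg.designated_modules),
                 cfg.asd_module_bias, 1.0)
    is_asd[_weighted_choice(rng, asd_pool, w, cfg.n_asd_genes)] = True

    biotype = np.where(rng.random(n_genes) < 0.9, "protein_coding", "other")
    lnc_kind = np.where(rng.random(n_genes) < 0.5, "antisense", "lincRNA")
    biotype = np.where(is_lnc, lnc_kind, biotype)

    annot = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "biotype": biotype,
            "is_lncRNA": is_lnc,
            "is_asd_risk": is_asd,
        }
    )

    truth = SimTruth(
        true_module=pd.Series(true_module, index=gene_ids, name="true_module"),
        eigengene_profiles=pd.DataFrame(
            trajectories,
            index=[f"M{m}" for m in range(1, cfg.n_modules + 1)],
            columns=sample_ids,
        ),
        planted_hub_lncRNAs=[gene_ids[i] for i in sorted(hub_idx)],
    )
    return expr, meta, annot, truth


def write_dataset(out_dir, expr: ExpressionMatrix, meta, annot, truth: SimTruth,
                  config: SimConfig | None = None) -> dict:
    """Write a generated dataset as TSV files (plus the config as YAML)."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "expression": os.path.join(out_dir, "expression.tsv"),
        "metadata": os.path.join(out_dir, "metadata.tsv"),
        "annotation": os.path.join(out_dir, "annotation.tsv"),
        "truth": os.path.join(out_dir, "truth.tsv"),
    }
    expr.to_tsv(paths["expression"])
    meta.to_csv(paths["metadata"], sep="\t", index=False)
    annot.to_csv(paths["annotation"], sep="\t", index=False)
    truth.true_module.to_frame().to_csv(paths["truth"], sep="\t", index_label="gene_id")
    if config is not None:
        paths["config"] = os.path.join(out_dir, "sim_config.yaml")
        config.to_yaml(paths["config"])
    return paths
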