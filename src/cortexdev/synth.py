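"""Synthetic cohorts with planted, recoverable structure.

Three generators emulate the inputs of the analysis stages so that every
downstream estimator can be validated against known ground truth:

* an imaging cohort (n=88, ages 8-19) with per-measure planted percent
  changes over age (f_neurite +11.91%, r_soma -1% by default), a
  pubertal stage generated as a noisy monotone function of age, and an
  optional raw-signal mode that maps each subject through the forward
  SANDI model plus Rician noise;
* two expression-dataset dialects — normalized microarray-like values
  (ages 0.5-72, no repeated donors) and log2 RPKM with donor random
  intercepts, RIN confounding and regional offsets (ages 0.5-40) —
  with cell-type gene modules following planted age trajectories
  (oligodendrocyte/excitatory up, astrocyte/microglia/endothelial/OPC
  down, inhibitory flat; oligodendrocyte and astrocyte curves cross at
  age 20 by default, matching the observed glial ratio shift);
* a scan-rescan repeatability table with planted between/within
  variance components.

Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset, GeneSetCollection
from .protocol import AcquisitionProtocol
from .sandi import add_rician_noise
from .signal import SandiParams, sandi_signal

__all__ = [
    "MeasureSpec",
    "ImagingCohortConfig",
    "generate_imaging_cohort",
    "cohort_signals",
    "ModuleSpec",
    "ExpressionSimConfig",
    "generate_expression_dataset",
    "RepeatabilityConfig",
    "generate_repeatability_set",
]


# ---------------------------------------------------------------------------
# imaging cohort
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MeasureSpec:
    """One cohort measure: baseline level, planted percent change across
    the age range, residual sd, and an additive male-minus-female shift."""

    baseline: float
    percent_change: float
    noise_sd: float
    sex_effect: float = 0.0


def _default_measures() -> dict[str, MeasureSpec]:
    # noise sds put the age R^2 of the microstructural measures near the
    # .4-.55 regime observed in vivo at n=88
    return {
        "f_neurite": MeasureSpec(0.32, 11.91, 0.0105),
        "f_soma": MeasureSpec(0.38, -2.0, 0.012),
        "f_extracellular": MeasureSpec(0.30, -2.0, 0.012),
        "r_soma": MeasureSpec(9.2, -1.0, 0.028),
        "cth": MeasureSpec(2.80, -5.0, 0.10),
        "surface_area": MeasureSpec(9.0e4, 0.0, 4.0e3, sex_effect=6.0e3),
        "gm_volume": MeasureSpec(2.5e5, -4.0, 1.5e4, sex_effect=1.5e4),
    }


@dataclass
class ImagingCohortConfig:
    """Configuration of the synthetic imaging cohort."""

    n_subjects: int = 88
    age_lo: float = 8.0
    age_hi: float = 19.0
    measures: dict[str, MeasureSpec] = field(default_factory=_default_measures)
    pdss_noise_sd: float = 0.6

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if not self.age_lo < self.age_hi:
            raise ValueError("invalid age range")
        for name, m in self.measures.items():
            if m.baseline <= 0 and m.percent_change != 0:
                raise ValueError(f"{name}: ratio-scale baseline must be positive")


def _pdss(age: np.ndarray, noise_sd: float, rng) -> np.ndarray:
    """Pubertal stage 1-5 as a rounded noisy sigmoid of age."""
    latent = 1.0 + 4.0 / (1.0 + np.exp(-(age - 12.0) / 1.5))
    latent = latent + rng.normal(0.0, noise_sd, age.shape)
    return np.clip(np.round(latent), 1, 5).astype(int)


def generate_imaging_cohort(
    cfg: ImagingCohortConfig | None = None, seed: int = 0
) -> pd.DataFrame:
    """One subject per row: id, age, sex, pdss and every measure.

    Each measure follows baseline * (1 + pct/100 * (age-lo)/(hi-lo))
    plus the sex shift (+-effect/2) and Gaussian noise; ages are uniform
    over the range. Deterministic under ``seed``.
    """
    cfg = cfg or ImagingCohortConfig()
    rng = np.random.default_rng(seed)
    n = cfg.n_subjects
    age = np.sort(rng.uniform(cfg.age_lo, cfg.age_hi, n))
    sex = rng.permutation(np.r_[["F"] * (n // 2), ["M"] * (n - n // 2)])
    table = pd.DataFrame(
        {
            "subject": [f"sub-{i:03d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "pdss": _pdss(age, cfg.pdss_noise_sd, rng),
        }
    )
    frac = (age - cfg.age_lo) / (cfg.age_hi - cfg.age_lo)
    for name, m in cfg.measures.items():
        signal = m.baseline * (1.0 + m.percent_change / 100.0 * frac)
        shift = np.where(sex == "M", 0.5, -0.5) * m.sex_effect
        table[name] = signal + shift + rng.normal(0.0, m.noise_sd, n)
    return table


def cohort_signals(
    table: pd.DataFrame,
    protocol: AcquisitionProtocol,
    snr: float = np.inf,
    seed: int = 0,
) -> np.ndarray:
    """Raw-signal mode: per-subject spherical-mean SANDI signals.

    Each subject's (f_neurite, f_soma, r_soma) row is mapped through the
    forward model (d_in=2, d_e=0.75) and Rician-corrupted at ``snr``.
    Returns an (n_subjects, n_shells) array.
    """
    rng = np.random.default_rng(seed)
    out = []
    for _, row in table.iterrows():
        params = SandiParams(
            float(np.clip(row["f_neurite"], 0, 1)),
            float(np.clip(row["f_soma"], 0, 1 - np.clip(row["f_neurite"], 0, 1))),
            float(np.clip(row["r_soma"], 1, 12)),
            2.0,
            0.75,
        )
        out.append(add_rician_noise(sandi_signal(protocol, params), snr, rng))
    return np.asarray(out)


# ---------------------------------------------------------------------------
# expression datasets
# ---------------------------------------------------------------------------

#: baseline log2 RPKM per cell-type module (study-reported means; the
#: endothelial level is not reported and is set between microglia and
#: inhibitory neurons).
_LOG2RPKM_BASELINES = {
    "excitatory": 4.15,
    "inhibitory": 2.94,
    "oligodendrocyte": 3.11,
    "opc": 3.01,
    "astrocyte": 3.70,
    "microglia": 1.96,
    "endothelial": 2.50,
}


@dataclass(frozen=True)
class ModuleSpec:
    """One cell-type gene module: linear age slope (units/year) and
    baseline level; genes in the module share the trajectory."""

    n_genes: int
    slope: float
    baseline: float = 0.0


def _default_modules(dialect: str) -> dict[str, ModuleSpec]:
    # oligodendrocyte/excitatory rise, astrocyte/microglia/endothelial/OPC
    # fall, inhibitory flat; on the log2 RPKM scale the oligodendrocyte and
    # astrocyte module curves cross at the observed age-20 ratio shift:
    # 3.11 + 0.018*a = 3.70 - 0.0115*a  =>  a = 0.59 / 0.0295 = 20.0
    if dialect == "rnaseq-log2rpkm":
        return {
            "excitatory": ModuleSpec(60, 0.020, _LOG2RPKM_BASELINES["excitatory"]),
            "inhibitory": ModuleSpec(60, 0.0, _LOG2RPKM_BASELINES["inhibitory"]),
            "oligodendrocyte": ModuleSpec(
                60, 0.018, _LOG2RPKM_BASELINES["oligodendrocyte"]
            ),
            "opc": ModuleSpec(60, -0.012, _LOG2RPKM_BASELINES["opc"]),
            "astrocyte": ModuleSpec(60, -0.0115, _LOG2RPKM_BASELINES["astrocyte"]),
            "microglia": ModuleSpec(60, -0.012, _LOG2RPKM_BASELINES["microglia"]),
            "endothelial": ModuleSpec(60, -0.012, _LOG2RPKM_BASELINES["endothelial"]),
        }
    # microarray Z-like scale
    return {
        "excitatory": ModuleSpec(60, 0.020),
        "inhibitory": ModuleSpec(60, 0.0),
        "oligodendrocyte": ModuleSpec(60, 0.030),
        "opc": ModuleSpec(60, -0.012),
        "astrocyte": ModuleSpec(60, -0.020),
        "microglia": ModuleSpec(60, -0.012),
        "endothelial": ModuleSpec(60, -0.012),
    }


@dataclass
class ExpressionSimConfig:
    """Configuration of the synthetic expression dataset."""

    dialect: str = "microarray-normalized"
    n_genes: int = 2000
    modules: dict[str, ModuleSpec] | None = None
    noise_sd: float = 1.0
    n_samples: int = 214  # microarray dialect
    age_lo: float = 0.5
    age_hi: float = 72.0
    n_donors: int = 20  # rnaseq dialect
    regions: tuple[str, ...] = ("DLPFC", "M1", "V1", "MFC", "ITC")
    donor_sd: float = 0.3
    rin_mean: float = 8.45
    rin_sd: float = 0.79
    rin_effect: float = 0.15
    region_offset_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.modules is None:
            self.modules = _default_modules(self.dialect)
            if self.dialect == "rnaseq-log2rpkm":
                self.noise_sd = 0.35
                self.age_hi = min(self.age_hi, 40.0)
        if self.noise_sd <= 0:
            raise ValueError("noise sd must be positive")
        if sum(m.n_genes for m in self.modules.values()) > self.n_genes:
            raise ValueError("module sizes exceed n_genes")


def generate_expression_dataset(
    cfg: ExpressionSimConfig | None = None, seed: int = 0
) -> tuple[ExpressionDataset, GeneSetCollection, pd.DataFrame]:
    """Dataset + cell-type gene sets + per-gene ground truth.

    Per-gene values are module_baseline + module_slope * age, plus (in
    the RNA-seq dialect) a donor random intercept, a RIN term and a
    region offset, plus Gaussian noise. The truth table flags genes with
    a nonzero planted slope as true age-genes. Module gene sets are
    pairwise disjoint; the universe is all simulated genes.
    """
    cfg = cfg or ExpressionSimConfig()
    rng = np.random.default_rng(seed)

    if cfg.dialect == "rnaseq-log2rpkm":
        donors = [f"donor-{i:02d}" for i in range(cfg.n_donors)]
        donor_age = rng.uniform(cfg.age_lo, cfg.age_hi, cfg.n_donors)
        donor_rin = np.clip(
            rng.normal(cfg.rin_mean, cfg.rin_sd, cfg.n_donors), 5.0, 10.0
        )
        donor_sex = rng.permutation(
            np.r_[["F"] * (cfg.n_donors // 2), ["M"] * (cfg.n_donors - cfg.n_donors // 2)]
        )
        rows = [
            (f"{d}_{r}", donor_age[i], r, donor_sex[i], donor_rin[i], d)
            for i, d in enumerate(donors)
            for r in cfg.regions
        ]
        samples = pd.DataFrame(
            rows, columns=["sample", "age", "region", "sex", "rin", "donor"]
        ).set_index("sample")
    else:
        n = cfg.n_samples
        samples = pd.DataFrame(
            {
                "age": np.sort(rng.uniform(cfg.age_lo, cfg.age_hi, n)),
                "region": "DLPFC",
                "sex": rng.permutation(np.r_[["F"] * (n // 2), ["M"] * (n - n // 2)]),
                "rin": np.clip(rng.normal(cfg.rin_mean, cfg.rin_sd, n), 5.0, 10.0),
                "donor": [f"donor-{i:03d}" for i in range(n)],
            },
            index=pd.Index([f"samp-{i:03d}" for i in range(n)], name="sample"),
        )

    age = samples["age"].to_numpy(float)
    n_samp = len(samples)

    gene_ids, truth_rows, sets = [], [], {}
    blocks = []
    g = 0
    for name, mod in cfg.modules.items():
        ids = [f"{name.upper()[:5]}{g + j:04d}" for j in range(mod.n_genes)]
        g += mod.n_genes
        sets[name] = frozenset(ids)
        gene_ids.extend(ids)
        curve = mod.baseline + mod.slope * age
        blocks.append(np.tile(curve, (mod.n_genes, 1)))
        truth_rows += [
            dict(gene=i, module=name, slope=mod.slope, is_age_gene=mod.slope != 0)
            for i in ids
        ]
    n_null = cfg.n_genes - g
    ids = [f"NULL{g + j:04d}" for j in range(n_null)]
    gene_ids.extend(ids)
    base_null = (
        rng.uniform(1.5, 4.5, n_null)[:, None]
        if cfg.dialect == "rnaseq-log2rpkm"
        else np.zeros((n_null, 1))
    )
    blocks.append(np.broadcast_to(base_null, (n_null, n_samp)).copy())
    truth_rows += [
        dict(gene=i, module="null", slope=0.0, is_age_gene=False) for i in ids
    ]

    X = np.vstack(blocks)
    if cfg.dialect == "rnaseq-log2rpkm":
        donor_eff = dict(
            zip(samples["donor"].unique(), rng.normal(0, cfg.donor_sd, cfg.n_donors))
        )
        region_eff = dict(
            zip(cfg.regions, rng.normal(0, cfg.region_offset_sd, len(cfg.regions)))
        )
        X = (
            X
            + np.array([donor_eff[d] for d in samples["donor"]])
            + np.array([region_eff[r] for r in samples["region"]])
            + cfg.rin_effect * (samples["rin"].to_numpy(float) - cfg.rin_mean)
        )
    X = X + rng.normal(0.0, cfg.noise_sd, X.shape)

    expr = pd.DataFrame(X, index=pd.Index(gene_ids, name="gene"), columns=samples.index)
    ds = ExpressionDataset(expr, samples, cfg.dialect)
    collection = GeneSetCollection(sets, frozenset(gene_ids), disjoint=True)
    truth = pd.DataFrame(truth_rows).set_index("gene")
    return ds, collection, truth


# ---------------------------------------------------------------------------
# repeatability
# ---------------------------------------------------------------------------


@dataclass
class RepeatabilityConfig:
    """Scan-rescan design with planted variance components."""

    n_subjects: int = 6
    n_sessions: int = 5
    between_sd: float = 3.0
    within_sd: float = 1.0
    mean: float = 0.0

    def __post_init__(self) -> None:
        if self.between_sd < 0 or self.within_sd < 0:
            raise ValueError("variance components must be non-negative")


def generate_repeatability_set(
    cfg: RepeatabilityConfig | None = None, seed: int = 0
) -> pd.DataFrame:
    """Long table (subject, session, value): value_ij = mean + u_i + e_ij."""
    cfg = cfg or RepeatabilityConfig()
    rng = np.random.default_rng(seed)
    u = rng.normal(0.0, cfg.between_sd, cfg.n_subjects)
    rows = []
    for i in range(cfg.n_subjects):
        e = rng.normal(0.0, cfg.within_sd, cfg.n_sessions)
        for j in range(cfg.n_sessions):
            rows.append(
                dict(
                    subject=f"sub-{i:02d}",
                    session=f"ses-{j:02d}",
                    value=cfg.mean + u[i] + e[j],
                )
            )
    return pd.DataFrame(rows)
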