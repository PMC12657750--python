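"""Synthetic study generator: designs, negative-binomial counts, diameters.

Emulates a three-arm bile-duct-ligation (BDL) study — sham + vehicle,
BDL + vehicle, BDL + ASBT-inhibitor — with treatment starting at one of
four disease stages (days 3/21/42/63 after surgery) and n = 5 mice per
group. Genes follow archetypes:

``RESCUED``
    deregulated by BDL, returned toward the sham mean under treatment by
    the stage's attenuation fraction (attenuation 1.0 = full return).
``PARTIAL``
    returned halfway relative to a rescued gene at the same stage.
``REFRACTORY``
    deregulated by BDL, unaffected by treatment.
``DRUG_ONLY``
    unaffected by BDL, shifted only in the treated arm.
``NULL``
    no effect anywhere.

Counts are gamma-Poisson (negative binomial) with per-gene dispersion and
log-normal library-size variation. Diameters are two-component log-normal
mixtures per stratum with a minority "dilated" component, mirroring the
heavy upper tail of bile-canalicular calibres under cholestasis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

ARMS = ("SHAM_VEH", "BDL_VEH", "BDL_TRT")
STAGES = ("S1", "S2", "S3", "S4")
#: Treatment-start day after surgery for each disease stage.
STAGE_DAYS = {"S1": 3, "S2": 21, "S3": 42, "S4": 63}
ORGANS = ("KIDNEY", "LIVER")

ARCHETYPES = ("RESCUED", "PARTIAL", "REFRACTORY", "DRUG_ONLY", "NULL")


@dataclass
class SimConfig:
    """Parameters of the count simulation.

    Attributes
    ----------
    n_genes : int
        Number of genes to simulate.
    n_per_group : int
        Replicates (mice) per arm x stage cell; the study design uses 5.
    baseline_mean_log2_range : tuple
        Per-gene baseline mean counts are ``2**U(a, b)`` at the nominal
        library size; default (3, 9) spans ~8-512 counts.
    dispersion : float or tuple
        Negative-binomial dispersion phi (var = mu + phi mu^2). A tuple is
        a per-gene log-uniform range; a scalar is shared by all genes.
        The default (0.005, 0.1) centres the biological coefficient of
        variation near 0.15, typical for genetically identical mice.
    archetype_fractions : mapping
        Proportions of the gene archetypes; must sum to 1.
    bdl_effect_log2_range : tuple
        |log2 fold change| of BDL-deregulated archetypes (random sign).
    rescue_attenuation : mapping
        Per-stage fraction of the BDL displacement undone by treatment in
        RESCUED genes; default decreases S1 -> S4, emulating the loss of
        therapeutic efficacy with later treatment start.
    library_size_sigma : float
        Log-normal sigma (natural log) of per-sample library-size
        variation around the design's nominal library size.
    seed : int
        Seed for all randomness; identical config + seed is bit-identical.
    """

    n_genes: int = 2000
    n_per_group: int = 5
    baseline_mean_log2_range: tuple[float, float] = (3.0, 9.0)
    dispersion: float | tuple[float, float] = (0.005, 0.1)
    archetype_fractions: Mapping[str, float] = field(
        default_factory=lambda: {
            "RESCUED": 0.25,
            "PARTIAL": 0.10,
            "REFRACTORY": 0.10,
            "DRUG_ONLY": 0.05,
            "NULL": 0.50,
        }
    )
    bdl_effect_log2_range: tuple[float, float] = (1.0, 4.0)
    rescue_attenuation: Mapping[str, float] = field(
        default_factory=lambda: {"S1": 1.0, "S2": 0.8, "S3": 0.5, "S4": 0.25}
    )
    library_size_sigma: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if not (isinstance(self.n_genes, (int, np.integer)) and self.n_genes > 0):
            raise ValueError(f"n_genes must be a positive integer, got {self.n_genes!r}")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2 (variance is undefined for n=1)")
        fracs = dict(self.archetype_fractions)
        unknown = set(fracs) - set(ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown archetypes: {sorted(unknown)}")
        if any(v < 0 for v in fracs.values()):
            raise ValueError("archetype fractions must be non-negative")
        total = sum(fracs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"archetype fractions must sum to 1, got {total}")
        for stage, a in self.rescue_attenuation.items():
            if not 0.0 <= a <= 1.0:
                raise ValueError(f"attenuation for {stage} must be in [0, 1], got {a}")
        disp = np.atleast_1d(np.asarray(self.dispersion, dtype=float))
        if np.any(disp <= 0):
            raise ValueError("dispersion must be positive")


def make_design(
    stages: Sequence[str] = STAGES,
    arms: Sequence[str] = ARMS,
    n_per_group: int = 5,
    organ: str = "KIDNEY",
    library_size: float = 1e6,
) -> pd.DataFrame:
    """Build the sample table: one row per replicate per (arm, stage).

    Returns a DataFrame with columns ``sample_id, arm, stage, organ,
    library_size`` in deterministic (stage-major, arm, replicate) order.
    """
    if len(stages) == 0 or len(arms) == 0:
        raise ValueError("stages and arms must be non-empty")
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2 (variance is undefined for n=1)")
    unknown_arms = set(arms) - set(ARMS)
    if unknown_arms:
        raise ValueError(f"unknown arms: {sorted(unknown_arms)}")
    unknown_stages = set(stages) - set(STAGES)
    if unknown_stages:
        raise ValueError(f"unknown stages: {sorted(unknown_stages)}")
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    rows = []
    for stage in stages:
        for arm in arms:
            for r in range(1, n_per_group + 1):
                rows.append(
                    {
                        "sample_id": f"{organ}_{stage}_{arm}_r{r}",
                        "arm": arm,
                        "stage": stage,
                        "organ": organ,
                        "library_size": float(library_size),
                    }
                )
    return pd.DataFrame(rows)


def _treated_log2fc(beta: np.ndarray, gamma: np.ndarray, archetype: np.ndarray, attenuation: float) -> np.ndarray:
    """log2 fold change of the treated arm vs sham for one stage.

    RESCUED genes have the BDL displacement multiplied by (1 - a); PARTIAL
    genes by (1 - a/2); REFRACTORY keep the full displacement; DRUG_ONLY
    genes are shifted only under treatment.
    """
    out = np.zeros_like(beta)
    out[archetype == "RESCUED"] = beta[archetype == "RESCUED"] * (1.0 - attenuation)
    out[archetype == "PARTIAL"] = beta[archetype == "PARTIAL"] * (1.0 - 0.5 * attenuation)
    out[archetype == "REFRACTORY"] = beta[archetype == "REFRACTORY"]
    out[archetype == "DRUG_ONLY"] = gamma[archetype == "DRUG_ONLY"]
    return out


def _archetype_assignment(n_genes: int, fractions: Mapping[str, float], rng: np.random.Generator) -> np.ndarray:
    """Largest-remainder integer allocation, then a seeded shuffle.

    Exact integer counts (rather than multinomial draws) keep the
    archetype composition of small simulations faithful to the config.
    """
    fracs = {a: fractions.get(a, 0.0) for a in ARCHETYPES}
    counts = {a: int(np.floor(f * n_genes)) for a, f in fracs.items()}
    short = n_genes - sum(counts.values())
    remainders = sorted(
        ARCHETYPES, key=lambda a: (fracs[a] * n_genes - counts[a], fracs[a]), reverse=True
    )
    for a in remainders[:short]:
        counts[a] += 1
    labels = np.concatenate([np.full(counts[a], a, dtype=object) for a in ARCHETYPES])
    rng.shuffle(labels)
    return labels


def simulate_counts(design: pd.DataFrame, cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a gene-by-sample count matrix and its ground-truth table.

    Parameters
    ----------
    design : DataFrame
        Sample table from :func:`make_design`.
    cfg : SimConfig

    Returns
    -------
    counts : DataFrame
        Integer counts, genes (index ``gene_id``) x samples (columns in
        design order).
    truth : DataFrame
        One row per gene per stage present in the design, with columns
        ``gene_id, stage, archetype, true_log2fc_bdl, true_log2fc_trt``.
    """
    cfg.validate()
    required = {"sample_id", "arm", "stage", "library_size"}
    missing = required - set(design.columns)
    if missing:
        raise ValueError(f"design is missing columns: {sorted(missing)}")

    rng = np.random.default_rng(cfg.seed)
    n_genes = int(cfg.n_genes)
    gene_ids = np.array([f"g{i:05d}" for i in range(n_genes)])

    archetype = _archetype_assignment(n_genes, cfg.archetype_fractions, rng)
    lo, hi = cfg.baseline_mean_log2_range
    baseline_mean = np.exp2(rng.uniform(lo, hi, n_genes))
    disp = np.asarray(cfg.dispersion, dtype=float)
    if disp.ndim == 0:
        dispersion = np.full(n_genes, float(disp))
    else:
        dlo, dhi = float(disp[0]), float(disp[1])
        dispersion = np.exp(rng.uniform(np.log(dlo), np.log(dhi), n_genes))

    elo, ehi = cfg.bdl_effect_log2_range
    magnitude = rng.uniform(elo, ehi, n_genes)
    sign = rng.choice([-1.0, 1.0], n_genes)
    deregulated = np.isin(archetype, ("RESCUED", "PARTIAL", "REFRACTORY"))
    beta = np.where(deregulated, sign * magnitude, 0.0)  # BDL vs sham, log2
    gamma = np.where(archetype == "DRUG_ONLY", sign * magnitude, 0.0)

    stages_present = list(dict.fromkeys(design["stage"]))
    truth_rows = []
    trt_lfc_by_stage: dict[str, np.ndarray] = {}
    for stage in stages_present:
        a = float(cfg.rescue_attenuation.get(stage, 1.0))
        trt = _treated_log2fc(beta, gamma, archetype, a)
        trt_lfc_by_stage[stage] = trt
        truth_rows.append(
            pd.DataFrame(
                {
                    "gene_id": gene_ids,
                    "stage": stage,
                    "archetype": archetype,
                    "true_log2fc_bdl": beta,
                    "true_log2fc_trt": trt,
                }
            )
        )
    truth = pd.concat(truth_rows, ignore_index=True)

    # Per-sample expected totals: nominal library size with log-normal noise.
    lib = design["library_size"].to_numpy(dtype=float)
    lib = lib * np.exp(rng.normal(0.0, cfg.library_size_sigma, len(design)))
    lib_ratio = lib / design["library_size"].to_numpy(dtype=float)

    mu = np.empty((n_genes, len(design)))
    for j, row in enumerate(design.itertuples(index=False)):
        if row.arm == "SHAM_VEH":
            lfc = 0.0
        elif row.arm == "BDL_VEH":
            lfc = beta
        elif row.arm == "BDL_TRT":
            lfc = trt_lfc_by_stage[row.stage]
        else:
            raise ValueError(f"unknown arm {row.arm!r} in design")
        mu[:, j] = baseline_mean * np.exp2(lfc) * lib_ratio[j]

    shape = 1.0 / dispersion[:, None]
    lam = rng.gamma(shape, mu / shape)
    counts = rng.poisson(lam)

    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=design["sample_id"].tolist())
    return counts_df, truth


def simulate_diameters(
    strata: Sequence[str],
    n_per_stratum: int | Mapping[str, int],
    base_lognormal_params: tuple[float, float] | Mapping[str, tuple[float, float]] = (0.0, 0.35),
    dilated_fraction: float | Mapping[str, float] = 0.1,
    dilated_shift: float | Mapping[str, float] = 1.2,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw stratified diameter measurements from a log-normal mixture.

    Each stratum (a treatment x timepoint experimental group) mixes a base
    log-normal component ``exp(N(mu, sigma))`` with a minority "dilated"
    component shifted by ``dilated_shift`` on the natural-log scale.

    Returns the measurement table (columns ``value``, ``stratum``) and a
    boolean truth array flagging dilated-component membership.
    """
    if len(strata) == 0:
        raise ValueError("strata must be non-empty")
    rng = np.random.default_rng(seed)

    def per_stratum(param, stratum):
        return param[stratum] if isinstance(param, Mapping) else param

    frames = []
    flags = []
    for stratum in strata:
        n = int(per_stratum(n_per_stratum, stratum))
        if n < 1:
            raise ValueError(f"n_per_stratum must be >= 1, got {n} for {stratum!r}")
        mu, sigma = per_stratum(base_lognormal_params, stratum)
        if sigma <= 0:
            raise ValueError(f"log-normal sigma must be positive, got {sigma} for {stratum!r}")
        frac = float(per_stratum(dilated_fraction, stratum))
        if not 0.0 <= frac < 1.0:
            raise ValueError(f"dilated_fraction must be in [0, 1), got {frac}")
        shift = float(per_stratum(dilated_shift, stratum))
        dilated = rng.random(n) < frac
        values = np.exp(rng.normal(mu + shift * dilated, sigma, n))
        frames.append(pd.DataFrame({"value": values, "stratum": stratum}))
        flags.append(dilated)
    ds = pd.concat(frames, ignore_index=True)
    return ds, np.concatenate(flags)
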