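"""Seeded synthetic cohorts with a latent oncogene-activity structure.

The generator emulates the statistical structure the scoring/survival
pipeline assumes in a MYC-high / immune-cold / poor-outcome cohort:

* each sample carries a latent activity ``a_j ~ Normal(0, 1)``;
* signature genes move with their planted direction:
  ``x_gj = d_g * beta_sig * a_j + Normal(0, sigma_noise)``;
* immune-module genes are coupled to activity through ``gamma_immune``
  (negative coupling models the immune-cold phenotype):
  ``x_gj = gamma_immune * a_j + noise``;
* background genes are pure noise;
* survival time is exponential with hazard
  ``baseline_hazard * exp(log_hr_high * 1[a_j > median(a)])`` and
  independent exponential censoring calibrated to ``censor_rate``.

All randomness flows from one seed through spawned substreams (activity,
signature noise, immune noise, background noise, survival, censoring), so
identical configs give bit-identical cohorts and changing one block's size
does not perturb the other blocks' draws.

A second generator, :func:`generate_de_tables`, plants a known concordant
gene set across several differential-expression tables for testing the
signature-derivation step.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import (
    SCALE_LOG2,
    DirectionalSignature,
    ExpressionMatrix,
    GeneSet,
    SurvivalTable,
)
from .signature import DETable


@dataclass
class CohortConfig:
    """Full parameterization of the synthetic cohort generator.

    Defaults describe a mid-sized bulk cohort: 200 samples, a 100-gene
    directional signature (50 up / 50 down), a 50-gene immune module
    strongly anticoupled to activity, 1850 background genes (2000 total),
    gene-level noise of 0.5 log2 units, and a High-vs-Low log hazard ratio
    of 0.7 with 20% censoring.
    """

    n_samples: int = 200
    n_sig_up: int = 50
    n_sig_down: int = 50
    n_immune_genes: int = 50
    n_background_genes: int = 1850
    beta_sig: float = 1.0          # log2 units per activity unit
    gamma_immune: float = -1.0     # immune <-> activity coupling
    sigma_noise: float = 0.5       # gene-level noise SD, log2 units
    baseline_hazard: float = 0.01  # events per day in the Low group
    log_hr_high: float = 0.7       # true log hazard ratio, High vs Low
    censor_rate: float = 0.2       # target fraction censored
    seed: int = 0

    def validate(self) -> None:
        problems = []
        for name in ("n_samples", "n_sig_up", "n_sig_down", "n_immune_genes",
                     "n_background_genes"):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be >= 0")
        if self.n_samples < 2:
            problems.append("n_samples must be >= 2")
        if self.n_sig_up + self.n_sig_down < 3:
            problems.append("n_sig_up + n_sig_down must be >= 3")
        if self.n_sig_up < 1 or self.n_sig_down < 1:
            problems.append("both signature directions need at least one gene")
        if self.beta_sig < 0:
            problems.append("beta_sig must be nonnegative")
        if self.sigma_noise <= 0:
            problems.append("sigma_noise must be positive")
        if self.baseline_hazard <= 0:
            problems.append("baseline_hazard must be positive")
        if not (0 <= self.censor_rate < 1):
            problems.append("censor_rate must lie in [0, 1)")
        if problems:
            raise ConfigError("; ".join(problems))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticCohort:
    """Generated cohort plus the planted ground truth."""

    expression: ExpressionMatrix = field(repr=False)
    activity: pd.Series = field(repr=False)      # latent a_j per sample
    signature: DirectionalSignature = field(repr=False)
    immune_set: GeneSet | None = field(repr=False)
    survival: SurvivalTable = field(repr=False)
    true_groups: pd.Series = field(repr=False)   # High iff a_j > median(a)
    config: CohortConfig = field(default_factory=CohortConfig)


def generate_cohort(cfg: CohortConfig) -> SyntheticCohort:
    """Draw a cohort under ``cfg``; deterministic given config + seed."""
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    s_act, s_sig, s_imm, s_bg, s_surv, s_cens = ss.spawn(6)
    n = cfg.n_samples

    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    a = np.random.default_rng(s_act).standard_normal(n)
    activity = pd.Series(a, index=sample_ids, name="activity")

    up_genes = [f"SIGUP{i + 1:04d}" for i in range(cfg.n_sig_up)]
    down_genes = [f"SIGDN{i + 1:04d}" for i in range(cfg.n_sig_down)]
    imm_genes = [f"IMM{i + 1:04d}" for i in range(cfg.n_immune_genes)]
    bg_genes = [f"BG{i + 1:04d}" for i in range(cfg.n_background_genes)]

    d = np.concatenate([np.ones(cfg.n_sig_up), -np.ones(cfg.n_sig_down)])
    n_sig = d.size
    x_sig = d[:, None] * cfg.beta_sig * a[None, :] + np.random.default_rng(
        s_sig
    ).normal(0.0, cfg.sigma_noise, (n_sig, n))
    x_imm = cfg.gamma_immune * a[None, :] + np.random.default_rng(s_imm).normal(
        0.0, cfg.sigma_noise, (cfg.n_immune_genes, n)
    )
    x_bg = np.random.default_rng(s_bg).normal(
        0.0, cfg.sigma_noise, (cfg.n_background_genes, n)
    )
    data = pd.DataFrame(
        np.vstack([x_sig, x_imm, x_bg]),
        index=up_genes + down_genes + imm_genes + bg_genes,
        columns=sample_ids,
    )
    expression = ExpressionMatrix(data, scale=SCALE_LOG2)

    signature = DirectionalSignature(
        name="planted_signature",
        entries={**{g: 1 for g in up_genes}, **{g: -1 for g in down_genes}},
    )
    immune_set = (
        GeneSet(name="planted_immune", description="immune module", genes=imm_genes)
        if cfg.n_immune_genes
        else None
    )

    high = a > np.median(a)
    true_groups = pd.Series(
        np.where(high, "High", "Low"), index=sample_ids, name="group"
    )
    hazard = cfg.baseline_hazard * np.exp(cfg.log_hr_high * high.astype(float))
    t_event = np.random.default_rng(s_surv).exponential(1.0 / hazard)
    if cfg.censor_rate > 0:
        # With exponential event time (rate l) and independent exponential
        # censoring (rate mu), P(censored) = mu / (l + mu); solving for the
        # cohort-average hazard gives mu = r / (1 - r) * mean(l).
        mu = cfg.censor_rate / (1.0 - cfg.censor_rate) * float(hazard.mean())
        t_cens = np.random.default_rng(s_cens).exponential(1.0 / mu, size=n)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    else:
        time = t_event
        event = np.ones(n, dtype=int)
    survival = SurvivalTable(
        pd.DataFrame(
            {"time": time, "event": event, "group": true_groups},
            index=sample_ids,
        )
    )
    return SyntheticCohort(
        expression=expression,
        activity=activity,
        signature=signature,
        immune_set=immune_set,
        survival=survival,
        true_groups=true_groups,
        config=cfg,
    )


def generate_de_tables(
    n_datasets: int = 2,
    n_shared: int = 50,
    n_specific: int = 100,
    n_null: int = 200,
    n_discordant: int = 0,
    seed: int = 0,
) -> tuple[list[DETable], DirectionalSignature | None, list[str]]:
    """Plant a concordant gene set across several DE tables.

    Returns the tables, the planted signature (shared genes with their
    common signs; None when ``n_shared == 0``), and the list of planted
    discordant genes (significant everywhere, sign flipped in the first
    table) for conflict-report tests. Each table also carries ``n_specific``
    private significant genes and ``n_null`` shared non-significant genes.
    """
    if n_datasets < 2:
        raise ValueError("need at least 2 datasets")
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    shared = [f"SHARED{i + 1:04d}" for i in range(n_shared)]
    shared_sign = rng.choice([1, -1], size=n_shared)
    disc = [f"DISC{i + 1:04d}" for i in range(n_discordant)]
    disc_sign = rng.choice([1, -1], size=n_discordant)
    null_genes = [f"NULLG{i + 1:04d}" for i in range(n_null)]

    def sig_rows(genes, signs):
        lfc = signs * rng.uniform(0.5, 3.0, size=len(genes))
        padj = rng.uniform(1e-8, 0.049, size=len(genes))
        return pd.DataFrame({"gene": genes, "log2fc": lfc, "padj": padj})

    tables = []
    for k in range(n_datasets):
        parts = [sig_rows(shared, shared_sign)]
        d_sign = -disc_sign if k == 0 else disc_sign
        if disc:
            parts.append(sig_rows(disc, d_sign))
        specific = [f"DS{k + 1}SPEC{i + 1:04d}" for i in range(n_specific)]
        parts.append(sig_rows(specific, rng.choice([1, -1], size=n_specific)))
        null_lfc = rng.uniform(-0.3, 0.3, size=n_null)
        parts.append(
            pd.DataFrame(
                {
                    "gene": null_genes,
                    "log2fc": null_lfc,
                    "padj": rng.uniform(0.2, 1.0, size=n_null),
                }
            )
        )
        df = pd.concat(parts, ignore_index=True)
        df = df.sample(frac=1.0, random_state=int(rng.integers(2**31)))
        tables.append(DETable(f"dataset_{k + 1}", df.reset_index(drop=True)))

    planted = (
        DirectionalSignature(
            name="planted_shared",
            entries={g: int(s) for g, s in zip(shared, shared_sign)},
        )
        if n_shared
        else None
    )
    return tables, planted, disc
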