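"""Synthetic cohorts with the statistical structure of a paired
primary/liver-metastasis methylation study.

The generative model separates methylation *frequency* from methylation
*density*. Each locus has a per-cohort frequency f_g: a patient's primary
tumor is latently methylated at that locus with probability f_g. Methylated
loci draw a density from a scaled Beta (broad, high mean); unmethylated loci
draw from a Beta with mass near zero. The matched metastasis starts as a
clone of the primary and then drifts:

* frequency gain — an unmethylated locus becomes methylated, at a per-month
  hazard ``r_gain`` over the primary-to-metastasis resection interval;
* frequency loss — a methylated locus reverts, at hazard ``r_loss``;
* density increase — a fraction of loci methylated in both tumors have
  their density inflated by a factor ``d`` (clipped at 100%).

Observed densities mix the tumor signal with a normal-cell baseline
(``purity`` x tumor + (1 - purity) x baseline), add Gaussian measurement
noise and clip to [0, 100]. Ground truth (latent states, event labels,
pre-noise densities) is emitted for recovery tests.

Two-channel array signals are simulated per pair: probe intensities
proportional to density plus background, log-normal probe noise, and a
smooth intensity-dependent dye bias to exercise lowess normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .matrix import MethylationMatrix

__all__ = [
    "SyntheticConfig", "SyntheticTruth", "ArraySignalConfig",
    "generate_cohort", "generate_array_signals", "PANEL_FREQUENCIES",
]

logger = logging.getLogger(__name__)

#: Default per-locus methylation frequencies for the 13-gene candidate panel,
#: spanning the spread seen in colorectal-tumor cohorts (rarely methylated
#: tumor suppressors up to frequently methylated age-related loci).
PANEL_FREQUENCIES: dict[str, float] = {
    "MINT1": 0.35, "MINT2": 0.40, "MINT31": 0.30, "MLH1": 0.10,
    "p16": 0.25, "p14": 0.20, "TIMP3": 0.20, "CDH1": 0.30,
    "CDH13": 0.45, "THBS1": 0.15, "MGMT": 0.35, "HPP1": 0.60,
    "ERalpha": 0.55,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort generator settings. Defaults emulate the study conditions:
    79 patients (36 without / 43 with liver metastasis), 16 matched pairs,
    13 candidate loci, >= 80% tumor-cell content, and intervals of 0-11
    months (synchronous) or 12-46 months (metachronous)."""

    n_patients: int = 79
    n_with_mets: int = 43
    n_pairs: int = 16
    n_loci: int = 13
    locus_ids: tuple[str, ...] | None = None
    #: per-locus methylation frequency; scalar broadcast, None uses the
    #: 13-gene panel defaults when n_loci == 13 (else 0.3)
    methylation_freq: float | tuple[float, ...] | None = None
    meth_beta: tuple[float, float] = (2.0, 2.0)     # scaled to [0, 100]
    unmeth_beta: tuple[float, float] = (1.0, 30.0)  # mass near 0
    purity: float = 0.9
    normal_baseline: float = 2.0    # percent, normal-cell methylation
    r_gain: float = 0.002           # per-locus per-month frequency-gain hazard
    r_loss: float = 0.0005          # per-locus per-month frequency-loss hazard
    density_inflation: float = 2.5  # factor d applied to inflated loci
    inflation_fraction: float = 0.25  # of loci methylated in both tumors
    metachronous_fraction: float = 7.0 / 43.0
    interval_months: tuple[float, ...] | None = None  # per paired patient
    noise_sd: float = 2.0           # percent
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.n_pairs <= self.n_with_mets <= self.n_patients):
            raise ValueError("need 0 < n_pairs <= n_with_mets <= n_patients")
        if not 0 < self.purity <= 1:
            raise ValueError("purity must be in (0, 1]")
        for name in ("r_gain", "r_loss", "metachronous_fraction",
                     "inflation_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.density_inflation < 1:
            raise ValueError("density_inflation must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for pair in (self.meth_beta, self.unmeth_beta):
            if not (pair[0] > 0 and pair[1] > 0):
                raise ValueError(f"invalid Beta parameters {pair}")

    def resolved_loci(self) -> tuple[str, ...]:
        if self.locus_ids is not None:
            if len(self.locus_ids) != self.n_loci:
                raise ValueError("locus_ids length must equal n_loci")
            return tuple(self.locus_ids)
        if self.n_loci == len(PANEL_FREQUENCIES):
            return tuple(PANEL_FREQUENCIES)
        return tuple(f"L{i:04d}" for i in range(self.n_loci))

    def resolved_freqs(self) -> np.ndarray:
        loci = self.resolved_loci()
        if self.methylation_freq is None:
            if set(loci) == set(PANEL_FREQUENCIES):
                f = np.array([PANEL_FREQUENCIES[l] for l in loci])
            else:
                f = np.full(self.n_loci, 0.3)
        elif np.isscalar(self.methylation_freq):
            f = np.full(self.n_loci, float(self.methylation_freq))
        else:
            f = np.asarray(self.methylation_freq, dtype=float)
            if f.shape != (self.n_loci,):
                raise ValueError("methylation_freq length must equal n_loci")
        if ((f < 0) | (f > 1)).any():
            raise ValueError("methylation frequencies must be in [0, 1]")
        return f


@dataclass
class SyntheticTruth:
    """Generator ground truth for recovery tests."""
    freqs: pd.Series                  # per-locus f_g
    pair_truth: pd.DataFrame          # per (paired patient, locus) states/events
    n_clipped: int                    # observed values clipped into [0, 100]


class Cohort(NamedTuple):
    matrix: MethylationMatrix
    meta: pd.DataFrame
    truth: SyntheticTruth


def _draw_density(rng: np.random.Generator, state: np.ndarray,
                  cfg: SyntheticConfig) -> np.ndarray:
    a1, b1 = cfg.meth_beta
    a0, b0 = cfg.unmeth_beta
    meth = rng.beta(a1, b1, size=state.shape) * 100.0
    unmeth = rng.beta(a0, b0, size=state.shape) * 100.0
    return np.where(state, meth, unmeth)


def _observe(rng: np.random.Generator, tumor: np.ndarray,
             cfg: SyntheticConfig) -> tuple[np.ndarray, int]:
    obs = cfg.purity * tumor + (1 - cfg.purity) * cfg.normal_baseline
    if cfg.noise_sd > 0:
        obs = obs + rng.normal(0.0, cfg.noise_sd, size=obs.shape)
    clipped = int(((obs < 0) | (obs > 100)).sum())
    return np.clip(obs, 0.0, 100.0), clipped


def generate_cohort(cfg: SyntheticConfig) -> Cohort:
    """Generate a methylation matrix, sample metadata and ground truth.

    One primary sample per patient; the first ``n_pairs`` liver-metastasis
    patients also get a matched metastasis sample. Reproducible: the same
    config (including seed) yields identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    loci = cfg.resolved_loci()
    freqs = cfg.resolved_freqs()
    patients = [f"P{i + 1:03d}" for i in range(cfg.n_patients)]
    lm_present = np.zeros(cfg.n_patients, dtype=bool)
    lm_present[:cfg.n_with_mets] = True
    paired = np.zeros(cfg.n_patients, dtype=bool)
    paired[:cfg.n_pairs] = True

    # clinical annotations
    if cfg.interval_months is not None:
        if len(cfg.interval_months) != cfg.n_with_mets:
            raise ValueError("interval_months length must equal n_with_mets")
        intervals = np.asarray(cfg.interval_months, dtype=float)
    else:
        meta_flag = rng.random(cfg.n_with_mets) < cfg.metachronous_fraction
        intervals = np.where(meta_flag,
                             rng.integers(12, 47, cfg.n_with_mets),
                             rng.integers(0, 12, cfg.n_with_mets)).astype(float)
    stage_no_lm = rng.choice([1, 2, 3], size=cfg.n_patients - cfg.n_with_mets,
                             p=[0.12, 0.65, 0.23])
    location = rng.choice(["proximal", "distal"], size=cfg.n_patients)

    # latent states and densities
    prim_state = rng.random((cfg.n_patients, cfg.n_loci)) < freqs
    prim_density = _draw_density(rng, prim_state, cfg)

    pair_intervals = intervals[:cfg.n_pairs]
    n_pairs = cfg.n_pairs
    gain_p = np.clip(cfg.r_gain * pair_intervals, 0.0, 1.0)[:, None]
    loss_p = np.clip(cfg.r_loss * pair_intervals, 0.0, 1.0)[:, None]
    gain_draw = rng.random((n_pairs, cfg.n_loci)) < gain_p
    loss_draw = rng.random((n_pairs, cfg.n_loci)) < loss_p
    inflate_draw = rng.random((n_pairs, cfg.n_loci)) < cfg.inflation_fraction

    prim_state_p = prim_state[:n_pairs]
    prim_density_p = prim_density[:n_pairs]
    gained = gain_draw & ~prim_state_p
    lost = loss_draw & prim_state_p & ~gained
    met_state = (prim_state_p | gained) & ~lost
    # multiplicative density increases act in the non-saturated regime:
    # loci whose inflated density would exceed 100% are left unchanged
    fits = prim_density_p * cfg.density_inflation <= 100.0
    inflated = (inflate_draw & prim_state_p & met_state
                & ~gained & ~lost & fits)

    met_density = prim_density_p.copy()
    new_meth = _draw_density(rng, np.ones_like(met_state), cfg)
    new_unmeth = rng.beta(*cfg.unmeth_beta, size=met_state.shape) * 100.0
    met_density[gained] = new_meth[gained]
    met_density[lost] = new_unmeth[lost]
    met_density[inflated] = prim_density_p[inflated] * cfg.density_inflation

    event = np.full((n_pairs, cfg.n_loci), "none", dtype=object)
    event[gained] = "frequency_gain"
    event[lost] = "frequency_loss"
    event[inflated & (cfg.density_inflation > 1)] = "density_increase"

    prim_obs, c1 = _observe(rng, prim_density, cfg)
    met_obs, c2 = _observe(rng, met_density, cfg)
    n_clipped = c1 + c2
    if n_clipped:
        logger.info("clipped %d observed densities into [0, 100]", n_clipped)

    sample_ids = [f"{p}_P" for p in patients] \
        + [f"{patients[i]}_M" for i in range(n_pairs)]
    values = np.vstack([prim_obs, met_obs])
    matrix = MethylationMatrix(
        pd.DataFrame(values, index=sample_ids, columns=list(loci)))

    rows = []
    lm_idx = 0
    stage_idx = 0
    for i, pid in enumerate(patients):
        if lm_present[i]:
            interval = intervals[lm_idx]
            timing = "metachronous" if interval >= 12 else "synchronous"
            stage = 4
            lm_idx += 1
        else:
            interval, timing, stage = np.nan, np.nan, stage_no_lm[stage_idx]
            stage_idx += 1
        rows.append({"sample_id": f"{pid}_P", "patient_id": pid,
                     "role": "primary", "stage": stage,
                     "location": location[i],
                     "liver_metastasis": "present" if lm_present[i] else "absent",
                     "timing": timing if lm_present[i] else "not_applicable",
                     "interval_months": interval})
    for i in range(n_pairs):
        pid = patients[i]
        interval = intervals[i]
        rows.append({"sample_id": f"{pid}_M", "patient_id": pid,
                     "role": "metastasis", "stage": 4,
                     "location": location[i],
                     "liver_metastasis": "not_applicable",
                     "timing": "metachronous" if interval >= 12 else "synchronous",
                     "interval_months": interval})
    meta = pd.DataFrame(rows)

    pair_truth = pd.DataFrame({
        "patient_id": np.repeat(patients[:n_pairs], cfg.n_loci),
        "locus_id": list(loci) * n_pairs,
        "primary_state": prim_state_p.ravel(),
        "metastasis_state": met_state.ravel(),
        "event": event.ravel(),
        "primary_density_true": prim_density_p.ravel(),
        "metastasis_density_true": met_density.ravel(),
        "interval_months": np.repeat(pair_intervals, cfg.n_loci),
    })
    truth = SyntheticTruth(freqs=pd.Series(freqs, index=list(loci)),
                           pair_truth=pair_truth, n_clipped=n_clipped)
    return Cohort(matrix=matrix, meta=meta, truth=truth)


@dataclass(frozen=True)
class ArraySignalConfig:
    """Two-channel array signal model settings."""
    probes_per_gene_mean: float = 2.8   # Poisson, floored at one probe
    intensity_scale: float = 100.0      # counts per percent methylation
    background: float = 5.0             # percent-equivalent background signal
    bias_amplitude: float = 0.8         # log2 units of dye bias vs intensity
    noise_sd: float = 0.25              # log2-scale probe noise SD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.probes_per_gene_mean < 1:
            raise ValueError("probes_per_gene_mean must be >= 1")
        if self.intensity_scale <= 0 or self.background <= 0:
            raise ValueError("intensity scale and background must be > 0")
        if self.noise_sd < 0 or self.bias_amplitude < 0:
            raise ValueError("noise_sd and bias_amplitude must be >= 0")


def generate_array_signals(truth: SyntheticTruth, cfg: ArraySignalConfig,
                           patients: Sequence[str] | None = None,
                           ) -> dict[str, pd.DataFrame]:
    """Simulate Cy3 (primary) / Cy5 (metastasis) probe intensities per pair.

    Probe intensities are proportional to true density plus background with
    log-normal probe noise; when ``bias_amplitude`` > 0 a smooth
    intensity-dependent multiplicative bias is applied to the Cy5 channel so
    the raw log-ratio depends on A until lowess-normalized. Expected log2
    ratio increases with the metastasis-primary density difference.
    """
    rng = np.random.default_rng(cfg.seed)
    pt = truth.pair_truth
    if patients is None:
        patients = list(dict.fromkeys(pt["patient_id"]))
    tables: dict[str, pd.DataFrame] = {}
    for pid in patients:
        sub = pt[pt["patient_id"] == pid]
        if len(sub) == 0:
            raise ValueError(f"no truth records for patient {pid!r}")
        genes = sub["locus_id"].to_numpy()
        prim = sub["primary_density_true"].to_numpy()
        met = sub["metastasis_density_true"].to_numpy()
        n_probes = np.maximum(
            1, rng.poisson(cfg.probes_per_gene_mean - 1, size=len(genes)) + 1)
        gidx = np.repeat(np.arange(len(genes)), n_probes)
        base3 = cfg.intensity_scale * (prim[gidx] + cfg.background)
        base5 = cfg.intensity_scale * (met[gidx] + cfg.background)
        cy3 = base3 * 2.0 ** rng.normal(0.0, cfg.noise_sd, size=gidx.size)
        cy5 = base5 * 2.0 ** rng.normal(0.0, cfg.noise_sd, size=gidx.size)
        if cfg.bias_amplitude > 0:
            a0 = 0.5 * (np.log2(cy5) + np.log2(cy3))
            u = (a0 - a0.mean()) / (a0.std() or 1.0)
            # slowly varying intensity-dependent bias, as on real two-color
            # arrays: monotone in A with saturating tails
            cy5 = cy5 * 2.0 ** (cfg.bias_amplitude * np.tanh(u))
        tables[pid] = pd.DataFrame({
            "probe_id": [f"{pid}_pr{i:06d}" for i in range(gidx.size)],
            "gene_id": genes[gidx],
            "cy3": cy3,
            "cy5": cy5,
        })
    return tables
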