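"""Synthetic cohort and trial generator.

Emulates the statistical structure of a trisomy-21 (T21) research cohort with
euploid (D21) controls — autoantibody bead-array MFI, plasma analyte panels
with detection limits, interferon-stimulated-gene (ISG) expression, immune
cell cluster compositions — plus a small open-label trial time-series with a
multiplicative treatment effect and sporadic immune-trigger spikes.

All randomness flows from a single root seed.  Each table draws from its own
fixed substream (``numpy.random.SeedSequence`` spawn keys), so adding or
regenerating one table never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from ._stats import bh_adjust

__all__ = [
    "AntigenParams",
    "AnalyteParams",
    "IsgParams",
    "ClusterParams",
    "TrialParams",
    "SyntheticConfig",
    "AntigenArray",
    "CohortBundle",
    "default_config",
    "generate_participants",
    "generate_antigen_array",
    "generate_analyte_table",
    "generate_expression_table",
    "generate_frequency_table",
    "generate_trial_series",
    "generate_cohort",
]

# Fixed substream keys: one per table so streams are independent and stable
# under extension.
_STREAMS = {
    "participants": 0,
    "antigens": 1,
    "analytes": 2,
    "expression": 3,
    "frequencies": 4,
    "trial": 5,
}


def _rng(seed: int, table: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAMS[table],))
    )


def _check_prob(p: float, name: str) -> None:
    if not (0.0 <= p <= 1.0):
        raise ConfigurationError(f"{name} must be a probability in [0, 1], got {p}")


@dataclass(frozen=True)
class AntigenParams:
    """Generative parameters for one bead-array antigen.

    background_loc/scale are on the natural-log MFI scale; ``pos_prob`` maps
    karyotype -> probability that a sample carries the autoantibody;
    ``pos_shift`` is the log-MFI elevation of a positive sample.
    """

    background_loc: float
    background_scale: float
    pos_prob: dict
    pos_shift: float

    def validate(self, name: str) -> None:
        for k, p in self.pos_prob.items():
            _check_prob(p, f"antigen {name} pos_prob[{k}]")
        if self.background_scale <= 0:
            raise ConfigurationError(f"antigen {name} background_scale must be > 0")


@dataclass(frozen=True)
class AnalyteParams:
    """Generative parameters for one plasma analyte (pg/mL)."""

    baseline_log2: float
    t21_log2fc: float = 0.0
    age_slope: float = 0.0  # log2 pg/mL per year
    plate_sd: float = 0.0
    lower_limit: float = 0.0
    upper_limit: float = np.inf

    def validate(self, name: str) -> None:
        if not self.lower_limit < self.upper_limit:
            raise ConfigurationError(
                f"analyte {name}: lower detection limit must be below upper"
            )


@dataclass(frozen=True)
class IsgParams:
    """Generative parameters for one gene (log2 FPKM scale)."""

    baseline_log2: float
    t21_log2fc: float = 0.0
    batch_sd: float = 0.0
    chr21: bool = False


@dataclass(frozen=True)
class ClusterParams:
    """Logistic-normal composition parameters for immune-cell clusters."""

    baseline: dict  # cluster -> proportion, sums to 1
    t21_log_odds: dict  # cluster -> additive logit-scale T21 effect
    sigma: float = 0.3  # logistic-normal sd

    def validate(self) -> None:
        total = float(sum(self.baseline.values()))
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"baseline composition must sum to 1 (got {total!r})"
            )
        if any(v <= 0 for v in self.baseline.values()):
            raise ConfigurationError("baseline proportions must be positive")
        if self.sigma < 0:
            raise ConfigurationError("cluster sigma must be >= 0")


@dataclass(frozen=True)
class TrialParams:
    """Open-label trial time-series parameters.

    ``treatment_log2fc`` maps measurement -> log2 fold-change applied at every
    post-baseline week.  ``trigger_events`` is a list of
    (participant_id, week, spike multiplier) tuples emulating immune triggers
    (vaccination, infection) that transiently elevate that visit's values.
    """

    n_participants: int = 10
    weeks: tuple = (0, 2, 8, 16)
    treatment_log2fc: dict = field(default_factory=dict)
    baseline_log2_mean: dict = field(default_factory=dict)
    baseline_log2_sd: dict = field(default_factory=dict)
    noise_sd: float = 0.1  # log2-scale visit noise
    trigger_events: tuple = ()
    # measurements a trigger perturbs; None means every measurement
    trigger_measurements: Optional[tuple] = None

    def validate(self) -> None:
        if 0 not in self.weeks:
            raise ConfigurationError("trial weeks must include the baseline week 0")
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        for m in self.treatment_log2fc:
            if m not in self.baseline_log2_mean:
                raise ConfigurationError(f"no baseline distribution for {m!r}")


@dataclass(frozen=True)
class SyntheticConfig:
    """Full generative description of a synthetic cohort."""

    seed: int
    n_t21: int = 120
    n_d21: int = 60
    age_range: tuple = (1.0, 57.0)
    sex_prob: float = 0.5  # probability of 'Female'
    prevalence: dict = field(default_factory=dict)  # condition -> {karyotype: p}
    antigen_params: dict = field(default_factory=dict)
    analyte_params: dict = field(default_factory=dict)
    isg_params: dict = field(default_factory=dict)
    cluster_params: Optional[ClusterParams] = None
    trial_params: Optional[TrialParams] = None
    # shared nuisance structure
    sample_background_sd: float = 0.3  # per-sample array background spread
    samples_per_plate: int = 40
    n_sources: int = 4
    source_sd: float = 0.2
    analyte_noise_sd: float = 0.5
    replicate_sd: float = 0.05
    n_batches: int = 3
    isg_noise_sd: float = 0.4

    def validate(self) -> None:
        if self.n_t21 + self.n_d21 < 2:
            raise ConfigurationError("need at least 2 participants in total")
        _check_prob(self.sex_prob, "sex_prob")
        if not self.age_range[0] < self.age_range[1]:
            raise ConfigurationError("age_range must be (min, max) with min < max")
        for cond, by_k in self.prevalence.items():
            for k, p in by_k.items():
                _check_prob(p, f"prevalence[{cond}][{k}]")
        for name, ap in self.antigen_params.items():
            ap.validate(name)
        for name, ap in self.analyte_params.items():
            ap.validate(name)
        if self.cluster_params is not None:
            self.cluster_params.validate()
        if self.trial_params is not None:
            self.trial_params.validate()


@dataclass(frozen=True)
class AntigenArray:
    """Bead-array data: raw MFI and bead counts (samples x antigens)."""

    mfi: pd.DataFrame
    bead_count: pd.DataFrame
    truth: Optional[pd.DataFrame] = None  # ground-truth positivity labels


@dataclass(frozen=True)
class CohortBundle:
    """Everything the downstream analyses consume, generated from one config."""

    participants: pd.DataFrame
    antigen_array: Optional[AntigenArray] = None
    analytes: Optional[pd.DataFrame] = None
    expression: Optional[pd.DataFrame] = None
    de_results: Optional[pd.DataFrame] = None
    frequencies: Optional[pd.DataFrame] = None
    trial: Optional[pd.DataFrame] = None


# ---------------------------------------------------------------------------
# default study conditions
# ---------------------------------------------------------------------------

def default_config(seed: int = 0) -> SyntheticConfig:
    """Study-condition defaults.

    Cohort sizes mirror the autoantibody array arm (120 T21 vs 60 euploid
    controls); condition prevalences follow the reported cohort rates (AITD
    ~53% of the T21 group, immune skin conditions ~43%, celiac ~10%).  A
    subset of antigens, analytes, genes and clusters carry true T21 effects
    of the magnitudes the analyses are designed to detect; the remainder are
    null features for calibration.
    """
    antigens: dict = {}
    # 8 truly enriched autoantibodies: common in T21, rare in controls
    for i in range(8):
        antigens[f"AAB{i + 1:03d}"] = AntigenParams(
            background_loc=6.2, background_scale=0.5,
            pos_prob={"T21": 0.40, "D21": 0.05}, pos_shift=3.0,
        )
    # 22 null antigens with equal low positivity in both groups
    for i in range(8, 30):
        antigens[f"AAB{i + 1:03d}"] = AntigenParams(
            background_loc=6.2, background_scale=0.5,
            pos_prob={"T21": 0.12, "D21": 0.12}, pos_shift=3.0,
        )

    analytes = {
        # the four cytokine-score components, elevated in T21
        "TNF-a": AnalyteParams(3.0, t21_log2fc=0.6, plate_sd=0.15,
                               lower_limit=0.1, upper_limit=5000.0),
        "IL-6": AnalyteParams(1.5, t21_log2fc=0.8, plate_sd=0.15,
                              lower_limit=0.1, upper_limit=5000.0),
        "CRP": AnalyteParams(20.0, t21_log2fc=0.7, age_slope=0.02,
                             plate_sd=0.15, lower_limit=10.0,
                             upper_limit=1e9),
        "IP-10": AnalyteParams(8.0, t21_log2fc=0.9, plate_sd=0.15,
                               lower_limit=1.0, upper_limit=1e6),
        # additional elevated markers
        "IL-22": AnalyteParams(2.0, t21_log2fc=0.5, plate_sd=0.15,
                               lower_limit=0.1, upper_limit=5000.0),
        "MCP-1": AnalyteParams(7.0, t21_log2fc=0.4, plate_sd=0.15,
                               lower_limit=1.0, upper_limit=1e6),
        # low-abundance analyte sitting near its detection limit, so the
        # below-range imputation path is exercised under default conditions
        "IL-17B": AnalyteParams(-1.0, t21_log2fc=0.3, plate_sd=0.15,
                                lower_limit=0.4, upper_limit=5000.0),
    }
    # null analytes for calibration
    for i in range(6):
        analytes[f"NULL{i + 1}"] = AnalyteParams(
            4.0, plate_sd=0.15, lower_limit=0.05, upper_limit=1e6
        )

    isgs: dict = {}
    # 16 true panel ISGs with T21 fold-changes spanning 1.5-3x
    panel_folds = np.linspace(np.log2(1.5), np.log2(3.0), 16)
    panel_names = [
        "RSAD2", "IFI44L", "IFI27", "IFIT1", "IFIT3", "ISG15", "OAS1",
        "OAS2", "OAS3", "IFI6", "SIGLEC1", "USP18", "LY6E", "HERC5",
        "BPGM", "EPSTI1",
    ]
    for g, fc in zip(panel_names, panel_folds):
        isgs[g] = IsgParams(6.0, t21_log2fc=float(fc), batch_sd=0.2)
    # chr21-encoded ISGs: strongly elevated but excluded from the panel
    for g in ("IFNAR2", "MX1", "MX2"):
        isgs[g] = IsgParams(6.0, t21_log2fc=1.2, batch_sd=0.2, chr21=True)
    # null genes
    for i in range(10):
        isgs[f"CTRL{i + 1}"] = IsgParams(6.0, batch_sd=0.2)

    clusters = ClusterParams(
        baseline={
            "B_cells": 0.10, "CD4_T": 0.25, "CD8_T": 0.15, "NK": 0.08,
            "monocytes": 0.12, "basophils": 0.02, "eosinophils": 0.04,
            "neutrophils": 0.24,
        },
        t21_log_odds={
            "B_cells": -0.5, "CD4_T": 0.0, "CD8_T": 0.0, "NK": 0.0,
            "monocytes": 0.0, "basophils": 0.7, "eosinophils": -0.6,
            "neutrophils": 0.0,
        },
        sigma=0.3,
    )

    trial = TrialParams(
        n_participants=10,
        weeks=(0, 2, 8, 16),
        treatment_log2fc={
            "IFN_score": -0.8, "cytokine_score": -0.5,
            "anti_TPO": -0.6, "anti_TG": -0.5,
        },
        baseline_log2_mean={
            # ~70% of anti-TPO baselines fall above the 60 U/mL ULN and
            # ~30% of anti-TG baselines above the 4 IU/mL ULN
            "IFN_score": 4.0, "cytokine_score": 2.5,
            "anti_TPO": np.log2(100.0), "anti_TG": np.log2(2.2),
        },
        baseline_log2_sd={
            "IFN_score": 0.5, "cytokine_score": 0.5,
            "anti_TPO": 1.2, "anti_TG": 1.5,
        },
        noise_sd=0.1,
        # immune-trigger spikes: one participant vaccinated days before the
        # week-8 draw, another with a respiratory infection before week 16;
        # they perturb the transcriptional/cytokine scores, not the titers
        trigger_events=(("P02", 8, 4.0), ("P04", 16, 4.0)),
        trigger_measurements=("IFN_score", "cytokine_score"),
    )

    return SyntheticConfig(
        seed=seed,
        n_t21=120,
        n_d21=60,
        prevalence={
            "AITD": {"T21": 0.531, "D21": 0.05},
            "skin_condition": {"T21": 0.43, "D21": 0.10},
            "celiac": {"T21": 0.096, "D21": 0.01},
        },
        antigen_params=antigens,
        analyte_params=analytes,
        isg_params=isgs,
        cluster_params=clusters,
        trial_params=trial,
    )


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_participants(config: SyntheticConfig) -> pd.DataFrame:
    """Participant metadata: id, karyotype, age, sex, condition flags."""
    config.validate()
    rng = _rng(config.seed, "participants")
    n = config.n_t21 + config.n_d21
    karyotype = ["T21"] * config.n_t21 + ["D21"] * config.n_d21
    ids = [f"{k}-{i + 1:04d}" for i, k in enumerate(karyotype)]
    lo, hi = config.age_range
    ages = rng.uniform(lo, hi, size=n)
    sex = np.where(rng.random(n) < config.sex_prob, "Female", "Male")
    df = pd.DataFrame({
        "sample_id": ids,
        "karyotype": karyotype,
        "age": np.round(ages, 2),
        "sex": sex,
        "cohort": "synthetic-HTP",
    })
    for cond, by_k in config.prevalence.items():
        p = np.array([by_k.get(k, 0.0) for k in karyotype])
        df[cond] = rng.random(n) < p
    return df


def generate_antigen_array(
    participants: pd.DataFrame, config: SyntheticConfig
) -> AntigenArray:
    """Bead-array MFI with sample-specific background and true positives."""
    config.validate()
    if not config.antigen_params:
        raise ConfigurationError("antigen_params is empty")
    rng = _rng(config.seed, "antigens")
    ids = participants["sample_id"].to_numpy()
    kary = participants["karyotype"].to_numpy()
    n = len(ids)
    antigens = list(config.antigen_params)
    sample_offset = rng.normal(0.0, config.sample_background_sd, size=n)
    log_mfi = np.empty((n, len(antigens)))
    truth = np.empty((n, len(antigens)), dtype=bool)
    for j, name in enumerate(antigens):
        ap = config.antigen_params[name]
        p = np.array([ap.pos_prob.get(k, 0.0) for k in kary])
        pos = rng.random(n) < p
        base = rng.normal(ap.background_loc, ap.background_scale, size=n)
        log_mfi[:, j] = base + sample_offset + ap.pos_shift * pos
        truth[:, j] = pos
    mfi = pd.DataFrame(np.exp(log_mfi), index=ids, columns=antigens)
    beads = pd.DataFrame(
        rng.poisson(60, size=(n, len(antigens))) + 20, index=ids, columns=antigens
    )
    return AntigenArray(
        mfi=mfi, bead_count=beads,
        truth=pd.DataFrame(truth, index=ids, columns=antigens),
    )


def generate_analyte_table(
    participants: pd.DataFrame, config: SyntheticConfig
) -> pd.DataFrame:
    """Long-format plasma analyte concentrations with censoring at limits.

    Each sample-analyte is measured in two replicate wells; wells whose
    calculated concentration falls outside the analyte's detection limits are
    recorded with a below/above-range flag and a missing value, never a
    clipped number.
    """
    config.validate()
    if not config.analyte_params:
        raise ConfigurationError("analyte_params is empty")
    rng = _rng(config.seed, "analytes")
    ids = participants["sample_id"].to_numpy()
    kary = participants["karyotype"].to_numpy()
    age = participants["age"].to_numpy()
    n = len(ids)
    # plate assignment is randomized across the cohort so plate effects do
    # not alias the karyotype contrast
    plate_slots = np.array(
        [f"plate{i // config.samples_per_plate + 1}" for i in range(n)]
    )
    plates = plate_slots[rng.permutation(n)]
    sources = np.array([f"source{s + 1}" for s in rng.integers(0, config.n_sources, n)])
    source_effects = {
        f"source{s + 1}": e
        for s, e in enumerate(rng.normal(0.0, config.source_sd, config.n_sources))
    }
    rows = []
    for name, ap in config.analyte_params.items():
        plate_ids = np.unique(plates)
        plate_eff = dict(zip(plate_ids, rng.normal(0.0, ap.plate_sd, len(plate_ids))))
        mu = (
            ap.baseline_log2
            + ap.t21_log2fc * (kary == "T21")
            + ap.age_slope * age
            + np.array([plate_eff[p] for p in plates])
            + np.array([source_effects[s] for s in sources])
            + rng.normal(0.0, config.analyte_noise_sd, n)
        )
        for well in (1, 2):
            conc = 2.0 ** (mu + rng.normal(0.0, config.replicate_sd, n))
            flag = np.where(
                conc < ap.lower_limit, "below",
                np.where(conc > ap.upper_limit, "above", "in"),
            )
            value = np.where(flag == "in", conc, np.nan)
            rows.append(pd.DataFrame({
                "sample_id": ids, "analyte": name, "plate": plates,
                "source": sources, "well": well, "value": value, "flag": flag,
            }))
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(
        ["analyte", "sample_id", "well"], kind="stable"
    ).reset_index(drop=True)


def generate_expression_table(
    participants: pd.DataFrame, config: SyntheticConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """FPKM-like expression (samples x genes) plus a DE results table.

    The DE table reports, per gene, the observed T21-vs-D21 log2 fold-change
    of mean log2(FPKM+1) expression (Welch t-test, BH-adjusted q) alongside
    the configured ground-truth fold-change and chr21 flag.
    """
    config.validate()
    if not config.isg_params:
        raise ConfigurationError("isg_params is empty")
    rng = _rng(config.seed, "expression")
    ids = participants["sample_id"].to_numpy()
    kary = participants["karyotype"].to_numpy()
    n = len(ids)
    batches = np.array([f"batch{b + 1}" for b in rng.integers(0, config.n_batches, n)])
    genes = list(config.isg_params)
    log2_fpkm = np.empty((n, len(genes)))
    for j, g in enumerate(genes):
        gp = config.isg_params[g]
        batch_ids = np.unique(batches)
        beff = dict(zip(batch_ids, rng.normal(0.0, gp.batch_sd, len(batch_ids))))
        log2_fpkm[:, j] = (
            gp.baseline_log2
            + gp.t21_log2fc * (kary == "T21")
            + np.array([beff[b] for b in batches])
            + rng.normal(0.0, config.isg_noise_sd, n)
        )
    fpkm = pd.DataFrame(2.0 ** log2_fpkm, index=ids, columns=genes)
    fpkm.insert(0, "batch", batches)

    # simple two-group DE on log2(FPKM + 1) to feed panel selection
    t21 = kary == "T21"
    x = np.log2(fpkm[genes].to_numpy() + 1.0)
    lfc, pvals = [], []
    for j in range(len(genes)):
        a, b = x[t21, j], x[~t21, j]
        lfc.append(a.mean() - b.mean())
        pvals.append(stats.ttest_ind(a, b, equal_var=False).pvalue)
    de = pd.DataFrame({
        "gene": genes,
        "log2fc": lfc,
        "q": bh_adjust(pvals),
        "true_log2fc": [config.isg_params[g].t21_log2fc for g in genes],
        "chr21": [config.isg_params[g].chr21 for g in genes],
    })
    return fpkm, de


def generate_frequency_table(
    participants: pd.DataFrame, config: SyntheticConfig
) -> pd.DataFrame:
    """Logistic-normal immune-cell cluster compositions, long format.

    Per sample, cluster logits are the log baseline composition plus a
    per-cluster T21 log-odds shift plus Gaussian noise; the softmax closes
    each row to sum exactly to 1.
    """
    config.validate()
    if config.cluster_params is None:
        raise ConfigurationError("cluster_params is not set")
    cp = config.cluster_params
    rng = _rng(config.seed, "frequencies")
    ids = participants["sample_id"].to_numpy()
    kary = participants["karyotype"].to_numpy()
    n = len(ids)
    clusters = list(cp.baseline)
    base_logit = np.log([cp.baseline[c] for c in clusters])
    shift = np.array([cp.t21_log_odds.get(c, 0.0) for c in clusters])
    logits = (
        base_logit[None, :]
        + shift[None, :] * (kary == "T21")[:, None]
        + rng.normal(0.0, cp.sigma, size=(n, len(clusters)))
    )
    expl = np.exp(logits - logits.max(axis=1, keepdims=True))
    props = expl / expl.sum(axis=1, keepdims=True)
    out = pd.DataFrame(props, index=ids, columns=clusters)
    long = out.reset_index(names="sample_id").melt(
        id_vars="sample_id", var_name="cluster", value_name="proportion"
    )
    long.insert(1, "level", "live")
    return long.sort_values(["cluster", "sample_id"], kind="stable").reset_index(
        drop=True
    )


def generate_trial_series(config: SyntheticConfig) -> pd.DataFrame:
    """Trial time-series: participant x week x measurement, long format.

    Baseline values are drawn from T21-like log-normal distributions; every
    post-baseline visit is multiplied by ``2**treatment_log2fc`` for its
    measurement plus multiplicative visit noise.  Configured trigger events
    multiply all of that participant-week's measurements by the spike factor
    and mark the visit with a ``trigger`` flag.
    """
    config.validate()
    if config.trial_params is None:
        raise ConfigurationError("trial_params is not set")
    tp = config.trial_params
    rng = _rng(config.seed, "trial")
    pids = [f"P{i + 1:02d}" for i in range(tp.n_participants)]
    triggers = {(p, w): m for p, w, m in tp.trigger_events}
    rows = []
    for meas, fc in tp.treatment_log2fc.items():
        mu = tp.baseline_log2_mean[meas]
        sd = tp.baseline_log2_sd.get(meas, 0.0)
        base = mu + (rng.normal(0.0, sd, len(pids)) if sd > 0 else 0.0)
        for i, pid in enumerate(pids):
            for week in sorted(tp.weeks):
                log2v = base[i]
                if week > 0:
                    log2v = log2v + fc
                    if tp.noise_sd > 0:
                        log2v = log2v + rng.normal(0.0, tp.noise_sd)
                value = 2.0 ** log2v
                flag = ""
                spiked = (tp.trigger_measurements is None
                          or meas in tp.trigger_measurements)
                if (pid, week) in triggers and spiked:
                    value *= triggers[(pid, week)]
                    flag = "trigger"
                rows.append((pid, week, meas, value, flag))
    return pd.DataFrame(
        rows, columns=["participant_id", "week", "measurement", "value", "flag"]
    )


def generate_cohort(config: SyntheticConfig) -> CohortBundle:
    """Generate every table of a cohort from one config (deterministic)."""
    participants = generate_participants(config)
    array = generate_antigen_array(participants, config) if config.antigen_params else None
    analytes = generate_analyte_table(participants, config) if config.analyte_params else None
    expression = de = None
    if config.isg_params:
        expression, de = generate_expression_table(participants, config)
    freqs = (
        generate_frequency_table(participants, config)
        if config.cluster_params is not None else None
    )
    trial = generate_trial_series(config) if config.trial_params is not None else None
    return CohortBundle(
        participants=participants, antigen_array=array, analytes=analytes,
        expression=expression, de_results=de, frequencies=freqs, trial=trial,
    )


def with_seed(config: SyntheticConfig, seed: int) -> SyntheticConfig:
    """Copy of ``config`` with a different root seed."""
    return replace(config, seed=seed)
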