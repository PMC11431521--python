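"""Synthetic case-control cohort generator.

Emulates the statistical structure of a suspected-lung-cancer cohort in which
plasma GAGomes were measured for everyone and cfDNA data for a subset:

* 85 lung-cancer cases (stage I/II/III/IV = 9/6/18/52) and 28 benign-disease
  controls;
* lognormal disaccharide concentrations in which only 0S CS and 4S CS have
  cohort medians above the 0.1 µg/mL limit of detection; cases show a higher
  0S CS concentration and a lower 4S CS mass fraction;
* additive experimental-batch and sample-age effects on log concentration;
* cfDNA concentration (log-scale) and somatic variant counts (negative
  binomial) elevated in cases with a stage-dependent shift (weak at stage I),
  drawn independently of the GAGome;
* availability masks: 81/113 samples with a cfDNA concentration, of which 74
  also have variant counts and 7 are insufficient for variant analysis;
* age / sex / smoking marginals loosely matching the study population.

Each component draws from its own child RNG stream, so adding one component
never perturbs another's draws, and a fixed seed reproduces the cohort
bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import PANEL_NAMES

STAGES = ("I", "II", "III", "IV")

#: Cohort-table column order.
SAMPLE_COLUMNS = (
    "group",
    "stage",
    "age_years",
    "sex",
    "smoking",
    "batch",
    "sample_age_months",
    "cfdna_conc",
    "cfdna_variants",
    "cfdna_status",
)


def _default_gagome_log_params() -> dict[str, tuple[float, float]]:
    # (log-mean, log-sd) per disaccharide for the control group, in ln µg/mL.
    # 0S CS and 4S CS sit well above the 0.1 µg/mL LOD (medians ≈ 0.6 and
    # 0.45); the other 15 disaccharides are near/below LOD (median ≈ 0.02).
    params = {name: (float(np.log(0.02)), 0.8) for name in PANEL_NAMES}
    params["0S CS"] = (float(np.log(0.60)), 0.45)
    params["4S CS"] = (float(np.log(0.45)), 0.40)
    return params


def _default_stage_counts() -> dict[str, int]:
    return {"I": 9, "II": 6, "III": 18, "IV": 52}


def _default_cfdna_stage_shifts() -> dict[str, float]:
    # Additive shift on ln cfDNA concentration, growing with stage so that
    # stage-I cases are barely separable from controls on cfDNA alone.
    return {"I": 0.0, "II": 0.35, "III": 0.6, "IV": 0.9}


def _default_variant_means() -> dict[str, float]:
    return {"I": 0.5, "II": 1.5, "III": 2.5, "IV": 4.5}


@dataclass
class SimulationParams:
    """Generating parameters of the synthetic cohort.

    Effect sizes for the two cancer-associated disaccharides are expressed in
    standardized log-scale units (multiples of that disaccharide's log-sd).
    """

    n_case: int = 85
    n_control: int = 28
    stage_counts: dict[str, int] = field(default_factory=_default_stage_counts)

    gagome_log_params: dict[str, tuple[float, float]] = field(
        default_factory=_default_gagome_log_params
    )
    delta_0s_cs: float = 0.6  # standardized case shift on ln(0S CS), > 0
    delta_4s_cs: float = -0.2  # standardized case shift on ln(4S CS), < 0

    n_batches: int = 2
    batch_log_shift: float = 0.15  # added to ln concentration in batch B
    batch_prob: float = 0.5  # P(batch B), independent of case status

    sample_age_range_months: tuple[float, float] = (0.0, 60.0)
    sample_age_slope: float = -0.002  # per month, on ln concentration

    lod: float = 0.1

    cfdna_log_mean: float = 1.8  # controls, ln ng/mL (median ≈ 6 ng/mL)
    cfdna_log_sd: float = 0.5
    cfdna_stage_shifts: dict[str, float] = field(default_factory=_default_cfdna_stage_shifts)
    variant_mean_control: float = 0.3
    variant_means_case: dict[str, float] = field(default_factory=_default_variant_means)
    variant_dispersion: float = 1.5  # negative-binomial size parameter

    n_with_cfdna: int = 81
    n_with_ngs: int = 74

    # Demographic marginals (cases, controls).
    age_mean: tuple[float, float] = (70.4, 67.0)
    age_sd: tuple[float, float] = (8.5, 14.4)
    p_female: tuple[float, float] = (0.529, 0.607)
    #: smoking probabilities (smoker, ex, never, missing)
    p_smoking_case: tuple[float, ...] = (0.353, 0.506, 0.141, 0.0)
    p_smoking_control: tuple[float, ...] = (0.179, 0.429, 0.321, 0.071)

    seed: int = 0

    @property
    def n_total(self) -> int:
        return self.n_case + self.n_control

    @property
    def n_insufficient(self) -> int:
        return self.n_with_cfdna - self.n_with_ngs

    def validate(self) -> None:
        if sum(self.stage_counts.values()) != self.n_case:
            raise ValueError(
                f"stage_counts sum {sum(self.stage_counts.values())} != n_case {self.n_case}"
            )
        if set(self.stage_counts) != set(STAGES):
            raise ValueError(f"stage_counts must cover stages {STAGES}")
        if not (0 <= self.n_with_ngs <= self.n_with_cfdna <= self.n_total):
            raise ValueError("availability counts must satisfy n_ngs <= n_cfdna <= n_total")
        for name, (_, sd) in self.gagome_log_params.items():
            if sd <= 0:
                raise ValueError(f"log-sd for {name} must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def default_params(seed: int = 0) -> SimulationParams:
    """The default study conditions (cohort sizes and structure as above)."""
    return SimulationParams(seed=seed)


def simulate_cohort(
    params: SimulationParams | None = None, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Draw one synthetic cohort.

    Returns ``(samples, gagome, truth)``: the per-sample metadata table
    (indexed by sample_id), the 17-column GAGome concentration table (µg/mL,
    canonical disaccharide names), and the realized generating parameters.
    """
    params = params or default_params()
    params.validate()
    if seed is None:
        seed = params.seed
    root = np.random.default_rng(seed)
    rng_cov, rng_gag, rng_cfdna, rng_avail = root.spawn(4)

    n = params.n_total
    ids = [f"S{i + 1:03d}" for i in range(n)]
    group = np.array(["case"] * params.n_case + ["control"] * params.n_control)
    is_case = group == "case"

    stage = np.array(["none"] * n, dtype=object)
    stage_list = [s for s in STAGES for _ in range(params.stage_counts[s])]
    stage[: params.n_case] = rng_cov.permutation(stage_list)

    # Demographics (feed only the cohort-characteristics statistics).
    age = np.where(
        is_case,
        rng_cov.normal(params.age_mean[0], params.age_sd[0], n),
        rng_cov.normal(params.age_mean[1], params.age_sd[1], n),
    ).round(1)
    sex = np.where(
        rng_cov.random(n) < np.where(is_case, params.p_female[0], params.p_female[1]),
        "female",
        "male",
    )
    smoking_levels = np.array(["smoker", "ex", "never", "missing"], dtype=object)
    smoking = np.empty(n, dtype=object)
    smoking[is_case] = rng_cov.choice(smoking_levels, is_case.sum(), p=params.p_smoking_case)
    smoking[~is_case] = rng_cov.choice(
        smoking_levels, (~is_case).sum(), p=params.p_smoking_control
    )

    batch = np.where(rng_cov.random(n) < params.batch_prob, "B", "A")
    lo, hi = params.sample_age_range_months
    sample_age = rng_cov.uniform(lo, hi, n).round(1)

    # GAGome concentrations: lognormal with case / batch / sample-age shifts.
    conc = pd.DataFrame(index=pd.Index(ids, name="sample_id"), columns=list(PANEL_NAMES), dtype=float)
    deltas = {"0S CS": params.delta_0s_cs, "4S CS": params.delta_4s_cs}
    for name in PANEL_NAMES:
        mu, sd = params.gagome_log_params[name]
        log_c = mu + sd * rng_gag.standard_normal(n)
        log_c += deltas.get(name, 0.0) * sd * is_case
        log_c += params.batch_log_shift * (batch == "B")
        log_c += params.sample_age_slope * sample_age
        conc[name] = np.exp(log_c)

    # cfDNA: independent stream; stage-dependent case shifts.
    stage_shift = np.array(
        [params.cfdna_stage_shifts.get(s, 0.0) for s in stage], dtype=float
    )
    cf_log = params.cfdna_log_mean + stage_shift + params.cfdna_log_sd * rng_cfdna.standard_normal(n)
    cfdna_conc = np.exp(cf_log).round(3)
    var_mean = np.where(
        is_case,
        np.array([params.variant_means_case.get(s, params.variant_mean_control) for s in stage]),
        params.variant_mean_control,
    ).astype(float)
    size = params.variant_dispersion
    variants = rng_cfdna.negative_binomial(size, size / (size + var_mean), n).astype(float)

    # Availability masks.
    with_cfdna = np.zeros(n, dtype=bool)
    chosen = rng_avail.choice(n, size=params.n_with_cfdna, replace=False)
    with_cfdna[chosen] = True
    insufficient = np.zeros(n, dtype=bool)
    insufficient[rng_avail.choice(chosen, size=params.n_insufficient, replace=False)] = True
    status = np.where(~with_cfdna, "missing", np.where(insufficient, "insufficient", "available"))
    cfdna_conc = np.where(with_cfdna, cfdna_conc, np.nan)
    variants = np.where(with_cfdna & ~insufficient, variants, np.nan)

    samples = pd.DataFrame(
        {
            "group": group,
            "stage": stage,
            "age_years": age,
            "sex": sex,
            "smoking": smoking,
            "batch": batch,
            "sample_age_months": sample_age,
            "cfdna_conc": cfdna_conc,
            "cfdna_variants": variants,
            "cfdna_status": status,
        },
        index=pd.Index(ids, name="sample_id"),
    )

    truth = {
        "seed": int(seed),
        "delta_0s_cs": params.delta_0s_cs,
        "delta_4s_cs": params.delta_4s_cs,
        "batch_log_shift": params.batch_log_shift,
        "sample_age_slope": params.sample_age_slope,
        "cfdna_stage_shifts": dict(params.cfdna_stage_shifts),
        "variant_means_case": dict(params.variant_means_case),
        "variant_mean_control": params.variant_mean_control,
        "gagome_log_params": {k: list(v) for k, v in params.gagome_log_params.items()},
    }
    return samples, conc, truth


def cohort_to_csv(
    samples: pd.DataFrame, gagome: pd.DataFrame, outdir: str | Path, truth: dict | None = None
) -> dict[str, Path]:
    """Write ``samples.csv``, ``gagome.csv`` (wide dialect) and ``truth.json``."""
    from .features import write_gagome_csv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"samples": outdir / "samples.csv", "gagome": outdir / "gagome.csv"}
    samples.to_csv(paths["samples"])
    write_gagome_csv(gagome, paths["gagome"])
    if truth is not None:
        paths["truth"] = outdir / "truth.json"
        paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True))
    return paths


def read_cohort_csv(samples_path: str | Path, gagome_path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Round-trip reader for :func:`cohort_to_csv` output."""
    from .features import read_gagome_csv

    samples = pd.read_csv(samples_path, index_col="sample_id")
    if len(samples) == 0:
        samples = samples.reindex(columns=list(SAMPLE_COLUMNS))
    gagome = read_gagome_csv(gagome_path)
    return samples, gagome
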