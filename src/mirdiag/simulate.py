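"""Synthetic RT-qPCR Ct-triplicate cohorts.

The raw per-sample Ct measurements behind the lung-tumor miRNA classifier
are not publicly deposited, so this module generates cohorts with the same
statistical structure the analysis assumes: per-sample technical triplicates
for four TaqMan assays (miR375-3p, miR205-5p, miR21-5p and the RNU6B
normalizer), class-conditional Gaussian ΔCt375 distributions for the two
tumor classes (non-neuroendocrine vs low-grade neuroendocrine), a stable
normalizer, small within-triplicate technical noise, and an optional rate of
injected technical outliers for benchmarking the QC stage.

The generative model works on the Ct scale.  For each sample a latent
ΔCt375 is drawn from its class Gaussian, a normalizer Ct from the U6
Gaussian, and the true miR375 Ct is set so that CtU6 − Ct375 equals the
drawn ΔCt375.  miR205 and miR21 are generated by an analogous latent-score
mechanism whose defaults give ΔCt205 *no* class separation (it discriminates
adenocarcinoma from squamous carcinoma, not NE from non-NE).  Independent
N(0, sigma_tech²) noise is then added to each of the three replicates of
every assay.  Amplification kinetics are not simulated; Ct values are drawn
directly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError

ASSAYS = ("miR375", "miR205", "miR21", "U6")

OUTLIER_MODES = ("inflated_variance", "shifted_replicate")

CT_COLUMNS = ["sample_id", "subtype", "class", "stage", "assay", "replicate", "ct"]

#: Clinical-stage frequencies of the study cohort (AJCC labels), used when a
#: spec does not override them; stages are drawn independently of ΔCt375.
DEFAULT_STAGE_WEIGHTS = {
    "IA1": 7, "IA2": 11, "IA3": 5, "IB": 18,
    "IIA": 3, "IIB": 11, "IIIA": 11, "IIIB": 5, "IVB": 1,
}


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults describe a "study-like" training cohort: 27 non-NE vs 31
    low-grade NE samples, class-conditional ΔCt375 Gaussians whose solved
    posterior-odds thresholds fall at ≈{1.4, 3.0, 4.9} (see
    :func:`mirdiag.fixtures.default_cohort_spec` for the derivation),
    a stable normalizer around 24 cycles, and 0.15 cycles of
    within-triplicate technical noise (typical TaqMan replicate SD).
    """

    n_per_class: dict[str, int] = field(
        default_factory=lambda: {"non-NE": 27, "NE": 31})
    subtype_weights: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "non-NE": {"AD": 14 / 27, "SQC": 13 / 27},
            "NE": {"AT": 8 / 31, "TC": 23 / 31},
        })
    mu_dct: dict[str, float] = field(
        default_factory=lambda: {"non-NE": 0.13, "NE": 5.57})
    sigma_dct: dict[str, float] = field(
        default_factory=lambda: {"non-NE": 2.39, "NE": 1.83})
    mu_u6: float = 24.0
    sigma_u6: float = 1.0
    # latent ΔCt205 = (Ct205 − CtU6) − 0.8·(Ct21 − CtU6); class-independent
    # by default so the miR205 score carries no NE/non-NE signal
    mu_dct205: float = 3.0
    sigma_dct205: float = 1.5
    mu_dct21: float = -2.0
    sigma_dct21: float = 1.0
    sigma_tech: float = 0.15
    outlier_rate: float = 0.0
    outlier_modes: tuple[str, ...] = OUTLIER_MODES
    variance_factor: float = 8.0
    replicate_shift: float = 4.0
    seed: int = 0
    stage_weights: dict[str, float] | None = field(
        default_factory=lambda: dict(DEFAULT_STAGE_WEIGHTS))
    ct_range: tuple[float, float] = (5.0, 40.0)
    round_ct: int | None = None

    def validate(self) -> None:
        for cls, n in self.n_per_class.items():
            if n < 1:
                raise ConfigurationError(f"n_per_class[{cls!r}] must be >= 1, got {n}")
        for cls in self.n_per_class:
            if cls not in self.mu_dct:
                raise ConfigurationError(f"mu_dct missing class {cls!r}")
            if cls not in self.sigma_dct:
                raise ConfigurationError(f"sigma_dct missing class {cls!r}")
            if cls not in self.subtype_weights:
                raise ConfigurationError(f"subtype_weights missing class {cls!r}")
        for name in ("sigma_u6", "sigma_dct205", "sigma_dct21", "sigma_tech"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {getattr(self, name)}")
        for cls, s in self.sigma_dct.items():
            if s < 0:
                raise ConfigurationError(f"sigma_dct[{cls!r}] must be >= 0, got {s}")
        if not 0.0 <= self.outlier_rate <= 1.0:
            raise ConfigurationError(f"outlier_rate must be in [0, 1], got {self.outlier_rate}")
        for mode in self.outlier_modes:
            if mode not in OUTLIER_MODES:
                raise ConfigurationError(
                    f"unknown outlier mode {mode!r}; valid modes: {OUTLIER_MODES}")
        if self.ct_range[0] >= self.ct_range[1]:
            raise ConfigurationError(f"ct_range must be increasing, got {self.ct_range}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["outlier_modes"] = list(self.outlier_modes)
        d["ct_range"] = list(self.ct_range)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortSpec":
        d = dict(d)
        if "outlier_modes" in d:
            d["outlier_modes"] = tuple(d["outlier_modes"])
        if "ct_range" in d:
            d["ct_range"] = tuple(d["ct_range"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown CohortSpec fields: {sorted(unknown)}")
        return cls(**d)


def _subtype_counts(weights: Mapping[str, float], n: int) -> dict[str, int]:
    """Largest-remainder allocation of n samples to subtypes."""
    names = list(weights)
    total = sum(weights.values())
    exact = np.array([weights[s] / total * n for s in names])
    counts = np.floor(exact).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(exact - counts), kind="stable")
    for i in order[:rem]:
        counts[i] += 1
    return dict(zip(names, counts))


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a raw Ct table (long format, one row per replicate).

    Deterministic given ``spec.seed``: each sample receives its own child
    random stream spawned from the master seed, so regenerating a cohort
    with more samples leaves earlier samples' values untouched.
    """
    spec.validate()
    n_total = sum(spec.n_per_class.values())
    children = np.random.SeedSequence(spec.seed).spawn(n_total)

    stage_names: list[str] = []
    stage_p: np.ndarray | None = None
    if spec.stage_weights:
        stage_names = list(spec.stage_weights)
        w = np.array([spec.stage_weights[s] for s in stage_names], dtype=float)
        stage_p = w / w.sum()

    rows: list[tuple] = []
    i = 0
    for cls, n in spec.n_per_class.items():
        counts = _subtype_counts(spec.subtype_weights[cls], n)
        subtypes = [s for s, c in counts.items() for _ in range(c)]
        for subtype in subtypes:
            i += 1
            rng = np.random.default_rng(children[i - 1])
            sample_id = f"S{i:04d}"
            dct375 = rng.normal(spec.mu_dct[cls], spec.sigma_dct[cls])
            ct_u6 = rng.normal(spec.mu_u6, spec.sigma_u6)
            dct21 = rng.normal(spec.mu_dct21, spec.sigma_dct21)
            dct205 = rng.normal(spec.mu_dct205, spec.sigma_dct205)
            true_ct = {
                "miR375": ct_u6 - dct375,
                "miR21": ct_u6 + dct21,
                "miR205": ct_u6 + dct205 + 0.8 * dct21,
                "U6": ct_u6,
            }
            stage = ""
            if stage_p is not None:
                stage = stage_names[rng.choice(len(stage_names), p=stage_p)]
            for assay in ASSAYS:
                noise = rng.normal(0.0, spec.sigma_tech, 3) if spec.sigma_tech > 0 \
                    else np.zeros(3)
                cts = np.clip(true_ct[assay] + noise, *spec.ct_range)
                if spec.round_ct is not None:
                    cts = np.round(cts, spec.round_ct)
                for rep in range(1, 4):
                    rows.append((sample_id, subtype, cls, stage, assay, rep,
                                 float(cts[rep - 1])))

    table = pd.DataFrame(rows, columns=CT_COLUMNS)
    if spec.outlier_rate > 0:
        table, _ = inject_technical_outliers(
            table, spec.outlier_rate, spec.outlier_modes, spec.seed + 1,
            variance_factor=spec.variance_factor,
            replicate_shift=spec.replicate_shift)
    return table


def inject_technical_outliers(
    table: pd.DataFrame,
    rate: float,
    modes: Sequence[str] = OUTLIER_MODES,
    seed: int = 0,
    variance_factor: float = 8.0,
    replicate_shift: float = 4.0,
) -> tuple[pd.DataFrame, list[dict]]:
    """Corrupt a Bernoulli(rate) selection of (sample, assay) triplicates.

    ``inflated_variance`` multiplies each replicate's deviation from the
    triplicate mean by ``variance_factor``; ``shifted_replicate`` adds
    ``replicate_shift`` cycles to one randomly chosen replicate.  Returns the
    corrupted table and the ground-truth list of corrupted triplicates
    (dicts with sample_id, assay, mode) for QC benchmarking.
    """
    if not 0.0 <= rate <= 1.0:
        raise ConfigurationError(f"outlier rate must be in [0, 1], got {rate}")
    modes = tuple(modes)
    for mode in modes:
        if mode not in OUTLIER_MODES:
            raise ConfigurationError(
                f"unknown outlier mode {mode!r}; valid modes: {OUTLIER_MODES}")
    if not modes:
        raise ConfigurationError("at least one outlier mode is required")
    validate_ct_table(table)

    out = table.copy()
    corrupted: list[dict] = []
    if rate == 0.0:
        return out, corrupted

    rng = np.random.default_rng(seed)
    # stable triplicate order: first appearance in the table
    keys = out[["sample_id", "assay"]].drop_duplicates()
    for _, (sample_id, assay) in keys.iterrows():
        if rng.random() >= rate:
            continue
        mode = modes[rng.integers(len(modes))] if len(modes) > 1 else modes[0]
        mask = (out["sample_id"] == sample_id) & (out["assay"] == assay)
        cts = out.loc[mask, "ct"].to_numpy()
        if mode == "inflated_variance":
            cts = cts.mean() + (cts - cts.mean()) * variance_factor
        else:
            j = rng.integers(len(cts))
            cts = cts.copy()
            cts[j] += replicate_shift
        out.loc[mask, "ct"] = cts
        corrupted.append({"sample_id": sample_id, "assay": assay, "mode": mode})
    return out, corrupted


def validate_ct_table(table: pd.DataFrame, ct_range: tuple[float, float] = (5.0, 40.0),
                      check_triplicates: bool = False) -> None:
    """Check that a raw Ct table has the expected columns and finite Cts."""
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"raw Ct table is missing columns {missing}")
    ct = table["ct"].to_numpy()
    if not np.all(np.isfinite(ct)):
        bad = table.loc[~np.isfinite(ct), "sample_id"].unique()[:5]
        raise ValidationError(f"non-finite Ct values for samples {list(bad)}")
    if np.any((ct < ct_range[0]) | (ct > ct_range[1])):
        raise ValidationError(
            f"Ct values outside plausible range {ct_range}; adjust ct_range if intended")
    if check_triplicates:
        sizes = table.groupby(["sample_id", "assay"]).size()
        if not (sizes == 3).all():
            bad = sizes[sizes != 3].index[:5].tolist()
            raise ValidationError(f"not exactly 3 replicates for {bad}")


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith(".tsv") else ","


def write_ct_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a raw Ct table as TSV/CSV (separator chosen by extension)."""
    table.to_csv(path, sep=_sep_for(path), index=False)


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a raw Ct table written by :func:`write_ct_table`."""
    table = pd.read_csv(path, sep=_sep_for(path),
                        dtype={"sample_id": str, "subtype": str, "class": str,
                               "stage": str},
                        keep_default_na=False, na_values=[])
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    table["replicate"] = table["replicate"].astype(int)
    table["ct"] = table["ct"].astype(float)
    return table[CT_COLUMNS + [c for c in table.columns if c not in CT_COLUMNS]]


def write_corruption_list(corrupted: list[dict], path: str | Path) -> None:
    Path(path).write_text(json.dumps(corrupted, indent=2) + "\n")


def read_corruption_list(path: str | Path) -> list[dict]:
    return json.loads(Path(path).read_text())
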