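"""Region-stratified synthetic cohorts with planted co-abundance structure.

The generator emulates the statistical shape of a large multi-region 16S
cohort: latent log absolute abundances are multivariate normal with a
planted correlation structure that may differ between hypertensive and
non-hypertensive participants and drift with hypertension grade; observed
counts are multinomial draws from the softmax composition at a log-normal
sequencing depth. Blood pressure is sampled within the assigned grade's
clinical band so that grade assignment round-trips exactly, and the eight
host covariates follow the cohort-level marginals (age ~ N(53, 15),
BMI ~ N(23.4, 3.5), 55% female, 33% smokers). Pathway abundances respond to
planted genus pairs through main effects plus a grade-dependent interaction
term, Y = a + b1*x1 + b2*x2 + gamma(grade)*x1*x2 + noise.

Every planted quantity is recorded in a ground-truth manifest so downstream
recovery can be scored without external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .data import CountTable, ValidationError, write_metadata, write_taxonomy

#: Default grade mix, proportional to the cohort's 4644/1425/581/259 split.
DEFAULT_GRADE_PROPORTIONS = (
    4644 / 6909,
    1425 / 6909,
    581 / 6909,
    259 / 6909,
)

PHYLA = (
    "Firmicutes",
    "Proteobacteria",
    "Bacteroidetes",
    "Actinobacteria",
    "Verrucomicrobia",
    "Fusobacteria",
    "Tenericutes",
    "Cyanobacteria",
)
#: Firmicutes-heavy phylum weighting, mirroring a gut genus panel.
PHYLUM_WEIGHTS = (0.58, 0.12, 0.10, 0.08, 0.04, 0.03, 0.03, 0.02)

_BP_BANDS = {
    # grade -> ((sbp_lo, sbp_hi), (dbp_lo, dbp_hi)) for the driving measure
    1: ((140.0, 159.9), (90.0, 99.9)),
    2: ((160.0, 179.9), (100.0, 109.9)),
    3: ((180.0, 219.9), (110.0, 129.9)),
}
_NORMAL_SBP = (100.0, 139.9)
_NORMAL_DBP = (60.0, 89.9)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults emulate the study conditions."""

    n_taxa: int = 60
    n_regions: int = 14
    #: samples per region for (non-hypertensive, hypertensive); an int means
    #: both groups equal. The default reproduces the cohort group totals
    #: (~4648 vs ~2352 over 14 regions).
    samples_per_region_group: tuple | int = (332, 168)
    grade_proportions: tuple = DEFAULT_GRADE_PROPORTIONS
    #: base correlation blocks: list of (start, size, rho)
    #: (a 4-block at rho = -0.3 keeps the compound-symmetry eigenvalue
    #: 1 + 3*rho positive)
    base_blocks: tuple = ((0, 4, 0.5), (4, 4, -0.3))
    #: (i, j, rho_control, rho_case, class)
    differential_edges: tuple = ()
    #: (i, j, rho_slope_per_grade)
    severity_edges: tuple = ()
    region_jitter_sd: float = 0.02
    depth_log_mean: float = float(np.log(30_000))
    depth_log_sd: float = 0.3
    latent_mean_sd: float = 1.0
    #: (pathway, i, j, beta1, beta2, gamma0, gamma_slope_per_grade, noise_sd)
    pathway_effects: tuple = ()
    n_null_pathways: int = 10
    female_fraction: float = 0.55
    smoking_rate: float = 0.33
    antibiotics_rate: float = 0.05
    diabetes_rate: float = 0.10
    hypercholesterolemia_rate: float = 0.10
    obesity_rate: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        props = np.asarray(self.grade_proportions, dtype=float)
        if props.size != 4 or abs(props.sum() - 1.0) > 1e-12 or (props < 0).any():
            raise ValidationError("grade_proportions must be 4 fractions summing to 1")
        if isinstance(self.samples_per_region_group, (int, np.integer)):
            self.samples_per_region_group = (
                int(self.samples_per_region_group),
                int(self.samples_per_region_group),
            )


@dataclass
class GroundTruthManifest:
    """Everything the generator planted, serializable to JSON losslessly."""

    config: dict
    correlations: dict  # "region|grade" -> correlation matrix (nested lists)
    differential_edges: list
    severity_edges: list
    pathway_effects: list
    taxa: list
    phyla: list
    latent: dict  # sample_id -> latent log-abundance vector

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=None, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "GroundTruthManifest":
        return cls(**json.loads(Path(path).read_text()))


def _base_correlation(config: SimulationConfig) -> np.ndarray:
    p = config.n_taxa
    R = np.eye(p)
    for start, size, rho in config.base_blocks:
        if start + size > p:
            raise ValidationError(f"base block ({start},{size}) exceeds n_taxa={p}")
        for i in range(start, start + size):
            for j in range(start, start + size):
                if i != j:
                    R[i, j] = rho
        vals = np.linalg.eigvalsh(R[start : start + size, start : start + size])
        if vals.min() <= 0:
            raise ValidationError(
                f"base correlation block ({start},{size},rho={rho}) not positive definite"
            )
    if np.linalg.eigvalsh(R).min() <= 0:
        raise ValidationError("base correlation matrix not positive definite")
    return R


def _grade_correlation(config: SimulationConfig, grade: int) -> np.ndarray:
    R = _base_correlation(config)
    for i, j, rho_control, rho_case, _cls in config.differential_edges:
        rho = rho_case if grade >= 1 else rho_control
        R[i, j] = R[j, i] = rho
    for i, j, slope in config.severity_edges:
        R[i, j] = R[j, i] = R[i, j] + slope * grade
    return R


def _jitter_correlation(R: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    if sd == 0:
        return R
    p = R.shape[0]
    for _ in range(200):
        noise = rng.normal(0.0, sd, size=(p, p))
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0.0)
        cand = np.clip(R + noise, -0.99, 0.99)
        np.fill_diagonal(cand, 1.0)
        if np.linalg.eigvalsh(cand).min() > 1e-6:
            return cand
    raise ValidationError("could not jitter correlation matrix to positive definite")


def _grade_counts(n_hyp: int, proportions: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of hypertensive samples to grades 1-3."""
    if n_hyp == 0 or proportions[1:].sum() == 0:
        return np.zeros(3, dtype=int)
    hyp_props = proportions[1:] / proportions[1:].sum()
    raw = hyp_props * n_hyp
    counts = np.floor(raw).astype(int)
    rem = n_hyp - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:rem]] += 1
    return counts


def _draw_bp(grade: int, rng: np.random.Generator) -> tuple[float, float]:
    if grade == 0:
        return rng.uniform(*_NORMAL_SBP), rng.uniform(*_NORMAL_DBP)
    (sbp_band, dbp_band) = _BP_BANDS[grade]
    if rng.random() < 0.5:  # SBP drives the grade
        return rng.uniform(*sbp_band), rng.uniform(*_NORMAL_DBP)
    return rng.uniform(*_NORMAL_SBP), rng.uniform(*dbp_band)


def simulate_cohort(config: SimulationConfig):
    """Draw a full synthetic cohort.

    Returns ``(counts, metadata, pathways, manifest)`` where counts is a
    :class:`CountTable`, metadata a DataFrame indexed by sample ID with
    blood pressure, region, grade, and the eight covariates, pathways a
    samples x pathways DataFrame, and manifest the ground truth.
    """
    rng = np.random.default_rng(config.seed)
    p = config.n_taxa
    taxa = [f"g{t:03d}" for t in range(p)]
    phyla = list(rng.choice(PHYLA, size=p, p=PHYLUM_WEIGHTS))
    taxonomy = pd.Series(phyla, index=taxa)
    mu = rng.normal(0.0, config.latent_mean_sd, size=p)

    n_non, n_hyp = config.samples_per_region_group
    props = np.asarray(config.grade_proportions, dtype=float)
    hyp_counts = _grade_counts(n_hyp, props)

    # planted correlation per grade (before regional jitter)
    grade_R = {g: _grade_correlation(config, g) for g in range(4)}

    sample_rows = []
    count_rows = []
    latent_store: dict[str, list] = {}
    correlations: dict[str, list] = {}
    sid = 0
    for region in range(config.n_regions):
        for grade in range(4):
            n_cell = int(n_non) if grade == 0 else int(hyp_counts[grade - 1])
            if n_cell == 0:
                continue
            R = _jitter_correlation(grade_R[grade], config.region_jitter_sd, rng)
            correlations[f"r{region:02d}|g{grade}"] = R.tolist()
            L = np.linalg.cholesky(R)
            eps = rng.standard_normal((n_cell, p))
            latent = mu + eps @ L.T
            comp = np.exp(latent - latent.max(axis=1, keepdims=True))
            comp /= comp.sum(axis=1, keepdims=True)
            depths = np.maximum(
                1, np.round(rng.lognormal(config.depth_log_mean, config.depth_log_sd, n_cell))
            ).astype(int)
            for k in range(n_cell):
                sample_id = f"s{sid:05d}"
                sid += 1
                counts = rng.multinomial(depths[k], comp[k])
                count_rows.append((sample_id, counts))
                latent_store[sample_id] = [float(v) for v in latent[k]]
                sbp, dbp = _draw_bp(grade, rng)
                sample_rows.append(
                    {
                        "sample_id": sample_id,
                        "region": f"r{region:02d}",
                        "sbp": round(sbp, 1),
                        "dbp": round(dbp, 1),
                        "grade": grade,
                        "hypertension": int(grade >= 1),
                        "age": float(np.clip(rng.normal(53.0, 15.0), 18, 95)),
                        "sex": int(rng.random() < config.female_fraction),
                        "bmi": float(np.clip(rng.normal(23.4, 3.5), 14, 45)),
                        "smoking": int(rng.random() < config.smoking_rate),
                        "antibiotics": int(rng.random() < config.antibiotics_rate),
                        "diabetes": int(rng.random() < config.diabetes_rate),
                        "hypercholesterolemia": int(
                            rng.random() < config.hypercholesterolemia_rate
                        ),
                        "obesity": int(rng.random() < config.obesity_rate),
                    }
                )

    metadata = pd.DataFrame(sample_rows).set_index("sample_id")
    counts_df = pd.DataFrame(
        np.vstack([c for _, c in count_rows]),
        index=[s for s, _ in count_rows],
        columns=taxa,
    )
    counts_df.index.name = "sample_id"
    table = CountTable(counts_df, taxonomy)

    # pathway responses on standardized latent scales
    latent_mat = np.array([latent_store[s] for s in counts_df.index])
    std_latent = (latent_mat - mu) / 1.0
    grades_arr = metadata["grade"].to_numpy()
    pathway_cols = {}
    for name, i, j, b1, b2, g0, g_slope, noise_sd in config.pathway_effects:
        gamma = g0 + g_slope * grades_arr
        pathway_cols[name] = (
            b1 * std_latent[:, i]
            + b2 * std_latent[:, j]
            + gamma * std_latent[:, i] * std_latent[:, j]
            + rng.normal(0.0, noise_sd, size=len(grades_arr))
        )
    for k in range(config.n_null_pathways):
        pathway_cols[f"null_pw{k:02d}"] = rng.standard_normal(len(grades_arr))
    pathways = pd.DataFrame(pathway_cols, index=counts_df.index)
    pathways.index.name = "sample_id"

    def _jsonify(v):
        if isinstance(v, (tuple, list)):
            return [_jsonify(x) for x in v]
        return v

    manifest = GroundTruthManifest(
        config={k: _jsonify(v) for k, v in asdict(config).items()},
        correlations=correlations,
        differential_edges=[list(e) for e in config.differential_edges],
        severity_edges=[list(e) for e in config.severity_edges],
        pathway_effects=[list(e) for e in config.pathway_effects],
        taxa=taxa,
        phyla=phyla,
        latent=latent_store,
    )
    return table, metadata, pathways, manifest


def write_cohort(outdir, table, metadata, pathways, manifest) -> None:
    """Write the four cohort files (TSV) plus the JSON manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_tsv(out / "counts.tsv")
    write_taxonomy(table.taxonomy, out / "taxonomy.tsv")
    write_metadata(metadata, out / "metadata.tsv")
    pathways.to_csv(out / "pathways.tsv", sep="\t")
    manifest.to_json(out / "manifest.json")
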