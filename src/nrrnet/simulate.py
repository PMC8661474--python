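"""Synthetic matched cohorts with known conditional-dependence structure.

The generator emulates the study design the pipeline is built for: a small
matched patient-control cohort measured for ~185 plasma lipids and ~20
inflammatory mediators (circulating proteins + inflammasome-pathway gene
expression), with

* a sparse Gaussian graphical model as ground truth — a positively
  intercorrelated "inflammasome core" among gene mediators plus a handful
  of strong, mostly negative mediator-lipid edges planted in the precision
  matrix;
* a shared pair-level random effect emulating age/sex matching (it cancels
  in the patient-minus-control fold change);
* per-feature mean shifts in patients for designated lipids (group
  effects, in units of latent SD);
* lognormal concentrations (latent Gaussian exponentiated base 2, so the
  log2 preprocessing step recovers the latent scale exactly);
* detection-limit left-censoring: per feature, the lowest
  ``censoring_quantile`` fraction of values is replaced by missing.

Because the planted precision pattern is known, every downstream stage
(NRR filtering, pruning, candidate extraction) can be scored against
ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io import (
    CatalogEntry,
    FeatureCatalog,
    FeatureTable,
    SampleMetadata,
    write_catalog,
    write_feature_table,
    write_metadata,
)
from .lipids import parse_lipid_name

#: shrinkage rounds allowed when forcing the requested precision pattern
#: to be positive-definite before giving up
MAX_SHRINK_ROUNDS = 200
_MIN_EIG = 1e-3

GENE_MEDIATOR_POOL = [
    "NLRP3", "PYCARD", "CASP1", "IL1RN", "IL18", "IL1B",
    "IL1A", "TNF", "IL6R", "NFKB1", "TLR4", "AIM2",
]
PLASMA_MEDIATOR_POOL = [
    "P-OPN", "P-IL-6", "P-CXCL8", "P-CXCL10", "P-IL-1Ra", "P-TNF-a",
    "P-IL-18", "P-MCP-1", "P-IL-10", "P-CRP", "P-IFN-g", "P-IL-17A",
]

# (class, carbon range, double-bond range, ether allowed) used to draw
# plausible sum-composition lipid names; weights roughly follow a plasma
# lipidome dominated by TGs and PCs
_LIPID_CLASS_SPECS = [
    ("TG", (42, 60), (0, 8), False, 0.30),
    ("PC", (30, 40), (0, 6), True, 0.20),
    ("LPC", (14, 24), (0, 4), False, 0.07),
    ("PE", (32, 42), (1, 7), True, 0.10),
    ("PI", (32, 40), (1, 5), False, 0.05),
    ("Cer", (32, 44), (1, 3), False, 0.09),
    ("SM", (30, 42), (1, 3), False, 0.10),
    ("ChoE", (16, 22), (0, 6), False, 0.09),
]


class GenerationError(RuntimeError):
    """The requested planted structure cannot be made positive-definite."""


@dataclass
class GroundTruth:
    """Planted structure of a synthetic cohort."""

    feature_ids: list[str]
    precision_matrix: np.ndarray
    planted_edges: list[tuple[str, str, float]]
    group_effects: dict[str, float]
    censoring_quantile: float
    seed: int
    catalog: FeatureCatalog = field(repr=False)

    def achieved_partial_correlation(self, feature_a: str, feature_b: str) -> float:
        """Partial correlation implied by the final precision matrix."""
        i = self.feature_ids.index(feature_a)
        j = self.feature_ids.index(feature_b)
        om = self.precision_matrix
        return float(-om[i, j] / np.sqrt(om[i, i] * om[j, j]))


@dataclass
class SyntheticCohort:
    table: FeatureTable
    metadata: list[SampleMetadata]
    catalog: FeatureCatalog
    truth: GroundTruth


# ---------------------------------------------------------------------------
# feature naming


def _draw_lipid_names(n: int, rng: np.random.Generator) -> list[str]:
    classes = [s[0] for s in _LIPID_CLASS_SPECS]
    weights = np.array([s[4] for s in _LIPID_CLASS_SPECS])
    weights = weights / weights.sum()
    specs = {s[0]: s for s in _LIPID_CLASS_SPECS}
    names: list[str] = []
    seen: set[str] = set()
    while len(names) < n:
        cls = classes[rng.choice(len(classes), p=weights)]
        _, crange, drange, ether_ok, _ = specs[cls]
        c = int(rng.integers(crange[0], crange[1] + 1))
        d = int(rng.integers(drange[0], drange[1] + 1))
        ether = ether_ok and rng.random() < 0.25
        name = f"{cls}({'O-' if ether else ''}{c}:{d})"
        if name not in seen:
            seen.add(name)
            names.append(name)
    return names


def _mediator_names(n_mediators: int, n_gene: int) -> tuple[list[str], list[str]]:
    n_plasma = n_mediators - n_gene
    genes = [
        GENE_MEDIATOR_POOL[i] if i < len(GENE_MEDIATOR_POOL) else f"GENE{i}"
        for i in range(n_gene)
    ]
    plasma = [
        PLASMA_MEDIATOR_POOL[i] if i < len(PLASMA_MEDIATOR_POOL) else f"P-M{i}"
        for i in range(n_plasma)
    ]
    return genes, plasma


# ---------------------------------------------------------------------------
# ground truth


def make_ground_truth(
    n_lipids: int = 185,
    n_mediators: int = 20,
    core_size: int = 6,
    n_planted_cross_edges: int = 10,
    negative_fraction: float = 0.73,
    effect_features: Mapping[str, float] | None = None,
    censoring_quantile: float = 0.05,
    seed: int = 0,
    core_strength: float = 0.18,
    cross_strength: tuple[float, float] = (0.5, 0.75),
    n_gene_mediators: int | None = None,
) -> GroundTruth:
    """Build a sparse precision matrix with a mediator core and cross edges.

    The core is a clique of positive partial correlations among the first
    ``core_size`` gene mediators (strength ~``core_strength``; within a
    6-clique 0.18 implies marginal correlations around 0.6, a tightly
    positively interconnected block). Cross mediator-lipid edges get
    magnitudes drawn uniformly from ``cross_strength`` and a negative sign
    with probability ``negative_fraction``; they are spread round-robin
    over the non-core mediators and distinct lipids. If the requested
    pattern is not positive-definite, off-diagonals are shrunk by 5% per
    round (up to a documented maximum) before giving up; the implied
    covariance is finally rescaled to unit diagonal.
    """
    if n_lipids < 1 or n_mediators < 0:
        raise GenerationError("counts must be positive")
    if core_size > n_mediators:
        raise GenerationError("core_size cannot exceed n_mediators")
    if not 0 <= censoring_quantile < 1:
        raise GenerationError("censoring_quantile must be in [0,1)")
    rng = np.random.default_rng(seed)

    if n_gene_mediators is None:
        n_gene_mediators = max(core_size, round(n_mediators * 9 / 20))
    genes, plasma = _mediator_names(n_mediators, n_gene_mediators)
    lipids = _draw_lipid_names(n_lipids, rng)
    feature_ids = lipids + genes + plasma
    entries = (
        [CatalogEntry(f, "lipid", f, parse_lipid_name(f)) for f in lipids]
        + [CatalogEntry(f, "mediator_gene", f) for f in genes]
        + [CatalogEntry(f, "mediator_plasma", f) for f in plasma]
    )
    catalog = FeatureCatalog(entries)

    p = len(feature_ids)
    index = {f: k for k, f in enumerate(feature_ids)}
    omega = np.eye(p)
    planted: list[tuple[str, str, float]] = []

    core = genes[:core_size]
    for a in range(core_size):
        for b in range(a + 1, core_size):
            target = core_strength * rng.uniform(0.9, 1.1)
            planted.append((core[a], core[b], target))

    cross_mediators = (genes[core_size:] + plasma) or genes
    if n_planted_cross_edges > 0:
        if n_planted_cross_edges > n_lipids:
            raise GenerationError("more cross edges requested than lipids available")
        chosen_lipids = rng.choice(n_lipids, size=n_planted_cross_edges, replace=False)
        for k, li in enumerate(chosen_lipids):
            med = cross_mediators[k % len(cross_mediators)]
            mag = rng.uniform(*cross_strength)
            sign = -1.0 if rng.random() < negative_fraction else 1.0
            planted.append((med, lipids[int(li)], sign * mag))

    for a, b, target in planted:
        omega[index[a], index[b]] = omega[index[b], index[a]] = -target

    shrink = 0
    while np.linalg.eigvalsh(omega).min() < _MIN_EIG:
        off = omega - np.diag(np.diag(omega))
        omega = np.diag(np.diag(omega)) + 0.95 * off
        shrink += 1
        if shrink > MAX_SHRINK_ROUNDS:
            raise GenerationError(
                "requested edge pattern cannot be made positive-definite "
                f"within {MAX_SHRINK_ROUNDS} shrinkage rounds"
            )

    # rescale implied covariance to unit diagonal (pure diagonal scaling:
    # preserves all partial and marginal correlations)
    sigma = np.linalg.inv(omega)
    d = np.sqrt(np.diag(sigma))
    sigma = sigma / d[:, None] / d[None, :]
    omega = np.linalg.inv(sigma)
    omega = (omega + omega.T) / 2

    return GroundTruth(
        feature_ids=feature_ids,
        precision_matrix=omega,
        planted_edges=planted,
        group_effects=dict(effect_features or {}),
        censoring_quantile=float(censoring_quantile),
        seed=int(seed),
        catalog=catalog,
    )


def default_ground_truth(seed: int = 0, **overrides) -> GroundTruth:
    """Study-sized ground truth: 185 lipids, 20 mediators (9 gene + 11
    plasma), a 6-gene inflammasome-like core, 10 mostly-negative cross
    edges, and +/-0.9 SD patient shifts on three designated lipids."""
    params = dict(
        n_lipids=185,
        n_mediators=20,
        core_size=6,
        n_planted_cross_edges=10,
        negative_fraction=0.73,
        censoring_quantile=0.05,
        seed=seed,
    )
    params.update(overrides)
    truth = make_ground_truth(**params)
    if not truth.group_effects:
        rng = np.random.default_rng(seed + 1)
        lipid_ids = [e.feature_id for e in truth.catalog if e.role == "lipid"]
        chosen = rng.choice(len(lipid_ids), size=min(3, len(lipid_ids)), replace=False)
        shifts = [0.9, 0.9, -0.9]
        truth.group_effects = {
            lipid_ids[int(i)]: shifts[k] for k, i in enumerate(chosen)
        }
    return truth


# ---------------------------------------------------------------------------
# cohort simulation


def simulate_cohort(
    truth: GroundTruth,
    n_pairs: int = 39,
    pair_effect_sd: float = 0.5,
    seed: int = 0,
    antipsychotic_fraction: float = 18 / 39,
    baseline_log2_range: tuple[float, float] = (3.0, 10.0),
) -> SyntheticCohort:
    """Draw a matched cohort from the ground-truth model.

    Each pair shares a per-feature latent shift (SD ``pair_effect_sd``,
    the matching effect); both members additionally receive independent
    multivariate normal draws with covariance = the inverse precision;
    patients get the planted group effects on top. Latents are
    exponentiated base 2 onto a concentration scale around per-feature
    baselines, then the lowest ``censoring_quantile`` fraction of each
    feature's values is censored to missing.
    """
    if n_pairs < 2:
        raise GenerationError("need at least 2 pairs (no variance estimable)")
    rng = np.random.default_rng(seed)
    p = len(truth.feature_ids)
    sigma = np.linalg.inv(truth.precision_matrix)
    sigma = (sigma + sigma.T) / 2
    L = np.linalg.cholesky(sigma)
    baseline = rng.uniform(*baseline_log2_range, size=p)
    effects = np.zeros(p)
    for f, shift in truth.group_effects.items():
        effects[truth.feature_ids.index(f)] = shift

    pair_shift = rng.normal(0.0, pair_effect_sd, size=(n_pairs, p))
    z_pat = rng.standard_normal((n_pairs, p)) @ L.T
    z_ctl = rng.standard_normal((n_pairs, p)) @ L.T
    lat_pat = baseline + pair_shift + z_pat + effects
    lat_ctl = baseline + pair_shift + z_ctl

    width = len(str(n_pairs))
    pair_ids = [f"pair{k + 1:0{width}d}" for k in range(n_pairs)]
    sample_ids: list[str] = []
    rows = []
    for k in range(n_pairs):
        sample_ids += [f"pt{k + 1:0{width}d}", f"ct{k + 1:0{width}d}"]
        rows += [lat_pat[k], lat_ctl[k]]
    values = np.exp2(np.array(rows))

    if truth.censoring_quantile > 0:
        n_samples = values.shape[0]
        n_censor = int(np.floor(truth.censoring_quantile * n_samples))
        if n_censor > 0:
            order = np.argsort(values, axis=0)
            for c in range(p):
                values[order[:n_censor, c], c] = np.nan

    n_flagged = int(round(antipsychotic_fraction * n_pairs))
    flagged = set(rng.choice(n_pairs, size=n_flagged, replace=False).tolist())
    metadata = []
    for k in range(n_pairs):
        metadata.append(
            SampleMetadata(f"pt{k + 1:0{width}d}", "patient", pair_ids[k], k in flagged)
        )
        metadata.append(SampleMetadata(f"ct{k + 1:0{width}d}", "control", pair_ids[k], False))

    table = FeatureTable(sample_ids, list(truth.feature_ids), values)
    return SyntheticCohort(table, metadata, truth.catalog, truth)


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, str]:
    """Write the cohort in the pipeline's input formats plus a truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "feature_table": str(out / "feature_table.tsv"),
        "metadata": str(out / "metadata.tsv"),
        "catalog": str(out / "catalog.tsv"),
        "ground_truth": str(out / "ground_truth.json"),
    }
    write_feature_table(cohort.table, paths["feature_table"])
    write_metadata(cohort.metadata, paths["metadata"])
    write_catalog(cohort.catalog, paths["catalog"])
    truth = cohort.truth
    with open(paths["ground_truth"], "w", encoding="utf-8") as fh:
        json.dump(
            {
                "planted_edges": [
                    {"feature_a": a, "feature_b": b, "target_partial_correlation": t}
                    for a, b, t in truth.planted_edges
                ],
                "group_effects": truth.group_effects,
                "censoring_quantile": truth.censoring_quantile,
                "seed": truth.seed,
            },
            fh,
            indent=2,
        )
    return paths
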