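"""Synthetic multi-series expression corpus with planted BCL2-family structure.

The generator emulates a pooled microarray compendium of mature B-cell
malignancies: ten entities plus their normal B-cell counterparts, spread
over several series (batches) and tissues of origin (PB/LN/BM/SPL), with
molecular subtypes, indolent/aggressive status including transformed
FL/MALT drawn from a DLBCL-like profile, multi-probe genes of heterogeneous
fidelity, a matched cell-line GEP/RNA-seq panel, and a monotone link
between a planted gene ratio and entity-level overall response rates.

The latent model for sample j and gene g is

    latent = baseline(g) + entity_effect(g, e) + tissue_effect(g, t)
             + subtype_effect(g, s) + batch_offset(series) + N(0, noise_sd)

and each probe observes ``fidelity * latent + (1 - fidelity) * noise``,
with an independent noise channel centered on the gene baseline. All values
are post-summarization log2 intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from bcl2panel.ratio import RatioSpec, SENSITIVITY_RATIO, ratio_score

# ---------------------------------------------------------------------------
# gene panels

#: The 12-gene BCL2-family panel retained for analysis.
BCL2_FAMILY_GENES: tuple[str, ...] = (
    "BCL2", "BCL2L1", "MCL1", "BCL2L2", "BCL2A1", "BIK",
    "PMAIP1", "BMF", "BID", "BCL2L11", "BAX", "BAK1",
)
#: Family members whose probes track nothing (fidelity 0) and drop out at QC.
ZERO_FIDELITY_GENES: tuple[str, ...] = ("BAD", "HRK")
#: Excluded up front for suspected microRNA cross-hybridization.
A_PRIORI_EXCLUDED_GENES: tuple[str, ...] = ("BBC3",)
#: Marker genes used to validate pooled normalization.
ANCHOR_GENES: tuple[str, ...] = (
    "CD27", "CCND1", "SOX11", "MKI67", "BCL6",
    "MME", "CD200", "ITGAE", "CD38", "SDC1",
)

MALIGNANT_ENTITIES: tuple[str, ...] = (
    "MCL", "BL", "DLBCL", "FL", "BPLL", "CLL", "HCL", "MALT", "SMZL", "MM",
)
NORMAL_ENTITIES: tuple[str, ...] = (
    "NaiveB", "MemoryB", "Centroblast", "Centrocyte", "MZB", "BMPC",
)

#: Cell-of-origin mapping from malignancy to normal counterpart.
DEFAULT_COUNTERPART_MAP: dict[str, str] = {
    "MCL": "NaiveB",       # pre-germinal-center neoplasm
    "BPLL": "NaiveB",
    "BL": "Centroblast",
    "DLBCL": "Centroblast",
    "FL": "Centrocyte",
    "CLL": "MemoryB",
    "HCL": "MemoryB",
    "MALT": "MZB",
    "SMZL": "MZB",
    "MM": "BMPC",
}

#: (gene, entity) anchoring-QC rules implied by histology.
DEFAULT_ANCHOR_RULES: tuple[tuple[str, str], ...] = (
    ("CCND1", "MCL"),
    ("SOX11", "MCL"),
    ("MKI67", "BL"),
    ("BCL6", "DLBCL"),
    ("MME", "FL"),
    ("CD200", "CLL"),
    ("CD27", "CLL"),
    ("ITGAE", "HCL"),
    ("CD38", "MM"),
    ("SDC1", "MM"),
)

AGGRESSIVE_ENTITIES: frozenset[str] = frozenset({"BL", "DLBCL", "MCL", "BPLL"})

TISSUES: tuple[str, ...] = ("PB", "LN", "BM", "SPL")


def _default_entity_counts() -> dict[str, int]:
    # roughly the pooled-corpus proportions: ~1,200 patients + 37 normals
    return {
        "MCL": 80, "BL": 40, "DLBCL": 200, "FL": 150, "BPLL": 15,
        "CLL": 300, "HCL": 30, "MALT": 60, "SMZL": 60, "MM": 250,
        "NaiveB": 6, "MemoryB": 6, "Centroblast": 6,
        "Centrocyte": 6, "MZB": 6, "BMPC": 7,
    }


def _default_tissue_mix() -> dict[str, dict[str, float]]:
    leukemic = {"PB": 0.8, "LN": 0.1, "BM": 0.1, "SPL": 0.0}
    nodal = {"PB": 0.1, "LN": 0.9, "BM": 0.0, "SPL": 0.0}
    mix = {
        "CLL": {"PB": 0.6, "LN": 0.25, "BM": 0.15, "SPL": 0.0},
        "BPLL": leukemic,
        "HCL": {"PB": 0.5, "LN": 0.0, "BM": 0.3, "SPL": 0.2},
        "MCL": {"PB": 0.5, "LN": 0.5, "BM": 0.0, "SPL": 0.0},
        "FL": {"PB": 0.15, "LN": 0.85, "BM": 0.0, "SPL": 0.0},
        "DLBCL": nodal,
        "BL": nodal,
        "MALT": nodal,
        "SMZL": {"PB": 0.4, "LN": 0.0, "BM": 0.0, "SPL": 0.6},
        "MM": {"PB": 0.0, "LN": 0.0, "BM": 1.0, "SPL": 0.0},
    }
    for e in NORMAL_ENTITIES:
        mix[e] = {"PB": 1.0, "LN": 0.0, "BM": 0.0, "SPL": 0.0}
    mix["BMPC"] = {"PB": 0.0, "LN": 0.0, "BM": 1.0, "SPL": 0.0}
    return mix


def _default_entity_effects() -> dict[str, dict[str, float]]:
    """Log2 shifts of panel genes per entity (normal counterparts at 0).

    Chosen to reproduce the qualitative biology the analysis expects:
    anti-apoptotic genes up and BH3-only genes down in malignancies, a
    BAX-up/BAK1-down switch, distinctive CLL and MM profiles, and planted
    (BCL2+BCL2L11+BAX)/BCL2L1 ratio medians decreasing from CLL and MCL
    (high) through FL (intermediate) to MM, DLBCL and BL (low). Anchor
    genes receive +3 log2 in their signature entities.
    """
    effects: dict[str, dict[str, float]] = {
        "BCL2": {
            "CLL": 2.5, "MCL": 2.0, "BPLL": 2.2, "HCL": 1.8, "FL": 1.5,
            "SMZL": 1.0, "MALT": 0.8, "DLBCL": 0.0, "MM": 0.0, "BL": -1.0,
        },
        "BCL2L11": {
            "CLL": -0.4, "MCL": -1.6, "FL": -0.2, "DLBCL": -0.4, "MM": -1.8,
            "BL": -0.2, "BPLL": -1.2, "HCL": -0.1, "SMZL": -1.1, "MALT": -0.5,
        },
        "BAX": {
            "CLL": 0.2, "MCL": 1.4, "FL": 0.3, "DLBCL": 1.0, "MM": 0.0,
            "BL": 0.1, "BPLL": 0.9, "HCL": 1.3, "SMZL": 0.4, "MALT": 1.1,
        },
        "BAK1": {e: -0.8 for e in MALIGNANT_ENTITIES} | {"MM": 0.3, "BL": 0.3},
        "BCL2L1": {
            "MM": 1.3, "DLBCL": 1.3, "BL": 1.2, "MCL": 0.5,
            "HCL": -0.4, "SMZL": 0.4, "BPLL": 0.1, "MALT": 0.2,
        },
        "MCL1": {"MM": 0.8, "DLBCL": 0.6, "CLL": 0.3},
        "BCL2A1": {"CLL": 1.5, "MCL": 0.8, "FL": 0.5, "MM": -1.5},
        "PMAIP1": {"CLL": 0.8},
        "BMF": {"CLL": 1.0},
        "BID": {"CLL": -1.5, "DLBCL": 0.3},
        "BIK": {},
        "BCL2L2": {},
    }
    for gene, entity in DEFAULT_ANCHOR_RULES:
        effects.setdefault(gene, {})[entity] = effects.get(gene, {}).get(entity, 0.0) + 3.0
    return effects


def _default_tissue_effects() -> dict[str, dict[str, float]]:
    # niche repression of BH3-only genes; BCL2L1 induction in lymph nodes
    return {
        "BCL2L11": {"LN": -1.2, "BM": -1.2, "SPL": -1.0},
        "PMAIP1": {"LN": -1.0, "BM": -1.0, "SPL": -0.8},
        "BCL2L1": {"LN": 0.8},
    }


def _default_subtypes() -> dict[str, dict[str, float]]:
    return {
        "MCL": {"SOX11pos": 0.8, "SOX11neg": 0.2},
        "DLBCL": {"GCB": 0.45, "ABC": 0.40, "PMBL": 0.15},
        "MM": {
            "CCND1": 0.15, "MS": 0.12, "MF": 0.07, "HY": 0.30,
            "PR": 0.12, "Myeloid": 0.08, "SOCS3": 0.06, "NFKB": 0.10,
        },
    }


def _default_subtype_effects() -> dict[str, dict[str, float]]:
    return {
        "BIK": {"SOX11neg": -2.0},
        "BCL2": {"CCND1": 1.5, "ABC": 1.0},
        # t(11;14) myeloma is Bcl-2-dependent with low Bcl-xL
        "BCL2L1": {"CCND1": -0.8},
        "BCL2L2": {"NFKB": 1.5},
        "BCL2L11": {"NFKB": 0.8},
        "BMF": {"NFKB": 1.0},
    }


# ---------------------------------------------------------------------------
# configuration


@dataclass
class SynthConfig:
    """Parameters of the synthetic corpus; defaults give the full-size design.

    Shifts are in log2 units. ``probe_plan`` fixes probe counts and
    fidelities for named genes; remaining ("filler") genes draw a probe
    count from `probes_per_gene` and fidelities from the default rule
    (first probe ~U(0.85, 0.95), extras ~U(0.3, 0.8)).
    """

    seed: int = 0
    n_probes: int = 5000
    n_genes: int = 1900
    probes_per_gene: tuple[int, ...] = (1, 2, 3, 4)
    entities: dict[str, int] = field(default_factory=_default_entity_counts)
    series_per_entity: int = 2
    tissue_mix: dict[str, dict[str, float]] = field(default_factory=_default_tissue_mix)
    entity_effects: dict[str, dict[str, float]] = field(default_factory=_default_entity_effects)
    tissue_effects: dict[str, dict[str, float]] = field(default_factory=_default_tissue_effects)
    subtypes: dict[str, dict[str, float]] = field(default_factory=_default_subtypes)
    subtype_effects: dict[str, dict[str, float]] = field(default_factory=_default_subtype_effects)
    counterpart_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_COUNTERPART_MAP))
    transformed_fraction: dict[str, float] = field(default_factory=lambda: {"FL": 0.25, "MALT": 0.25})
    batch_sd: float = 0.3
    noise_sd: float = 0.5
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    probe_noise_sd: float = 1.0
    probe_plan: dict[str, list[float]] = field(default_factory=dict)
    planted_ratio: RatioSpec = field(default_factory=lambda: SENSITIVITY_RATIO)
    orr_link_slope: float = 20.0
    orr_link_intercept: float | None = None
    n_celllines: int = 19
    cellline_sd: float = 1.0

    def validate(self) -> None:
        if not self.entities:
            raise ValueError("entity list must be non-empty")
        if any(n <= 0 for n in self.entities.values()):
            raise ValueError("entity sample counts must be positive")
        for e in self.entities:
            mix = self.tissue_mix.get(e)
            if mix is None:
                raise ValueError(f"no tissue mix for entity {e!r}")
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"tissue proportions for {e!r} must sum to 1")
        for gene, fids in self.probe_plan.items():
            if any(not (0.0 <= f <= 1.0) for f in fids):
                raise ValueError(f"probe fidelities for {gene!r} must lie in [0, 1]")
        named = self._named_genes()
        if self.n_genes < len(named):
            raise ValueError(
                f"n_genes={self.n_genes} below the {len(named)} named panel genes"
            )
        for g in self.planted_ratio.genes:
            if g not in named:
                raise ValueError(f"planted ratio gene {g!r} not in the gene panel")

    def _named_genes(self) -> list[str]:
        named = list(
            BCL2_FAMILY_GENES + ZERO_FIDELITY_GENES + A_PRIORI_EXCLUDED_GENES + ANCHOR_GENES
        )
        for g in self.probe_plan:
            if g not in named:
                named.append(g)
        return named

    def gene_list(self) -> list[str]:
        named = self._named_genes()
        fillers = [f"GENE{i:05d}" for i in range(1, self.n_genes - len(named) + 1)]
        return named + fillers


def default_config(seed: int = 0, **overrides) -> SynthConfig:
    """Full-size default configuration with optional field overrides."""
    cfg = SynthConfig(seed=seed, **overrides)
    cfg.validate()
    return cfg


def demo_config(seed: int = 0, samples_per_entity: int = 20, **overrides) -> SynthConfig:
    """Reduced configuration for quick runs: 10 entities, small panel."""
    counts = {e: samples_per_entity for e in MALIGNANT_ENTITIES}
    counts.update({e: max(4, samples_per_entity // 3) for e in NORMAL_ENTITIES})
    overrides.setdefault("entities", counts)
    overrides.setdefault("n_probes", 300)
    overrides.setdefault("n_genes", 120)
    cfg = SynthConfig(seed=seed, **overrides)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class GroundTruth:
    """Everything the generator planted, for recovery tests.

    ``latent`` is the noise-bearing gene-by-sample matrix before the probe
    layer; ``implied_orr`` maps each malignant entity to the ORR implied by
    the linear link on the entity median of the planted ratio.
    """

    latent: pd.DataFrame
    probe_fidelity: pd.Series
    baselines: pd.Series
    batch_offsets: dict[str, float]
    entity_effects: dict[str, dict[str, float]]
    tissue_effects: dict[str, dict[str, float]]
    planted_ratio: RatioSpec
    implied_orr: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "probe_fidelity": self.probe_fidelity.to_dict(),
            "baselines": self.baselines.to_dict(),
            "batch_offsets": self.batch_offsets,
            "entity_effects": self.entity_effects,
            "tissue_effects": self.tissue_effects,
            "planted_ratio": {
                "numerator": list(self.planted_ratio.numerator),
                "denominator": list(self.planted_ratio.denominator),
            },
            "implied_orr": self.implied_orr,
        }


# ---------------------------------------------------------------------------
# generation


def _probe_layout(cfg: SynthConfig, rng: np.random.Generator) -> tuple[list[str], pd.Series, pd.Series]:
    """Assign probes to genes and fidelities to probes, exactly n_probes rows."""
    genes = cfg.gene_list()
    counts: dict[str, int] = {}
    fidelities: dict[str, list[float]] = {}
    for g in genes:
        if g in cfg.probe_plan:
            fids = list(cfg.probe_plan[g])
        elif g in ZERO_FIDELITY_GENES:
            fids = [0.0, 0.0]
        elif g in A_PRIORI_EXCLUDED_GENES:
            fids = [float(rng.uniform(0.1, 0.3))]
        elif g in BCL2_FAMILY_GENES:
            fids = [float(rng.uniform(0.85, 0.95)), float(rng.uniform(0.3, 0.8))]
        elif g in ANCHOR_GENES:
            fids = [float(rng.uniform(0.85, 0.95))]
        else:
            k = int(rng.choice(cfg.probes_per_gene))
            fids = [float(rng.uniform(0.85, 0.95))] + [
                float(rng.uniform(0.3, 0.8)) for _ in range(k - 1)
            ]
        counts[g] = len(fids)
        fidelities[g] = fids
    total = sum(counts.values())
    if total > cfg.n_probes:
        raise ValueError(
            f"probe demand {total} exceeds n_probes={cfg.n_probes}; "
            "raise n_probes or lower n_genes"
        )
    # distribute the remainder over filler genes, capped at 4 probes each
    fillers = [g for g in genes if g.startswith("GENE")]
    i = 0
    while total < cfg.n_probes:
        if not fillers:
            raise ValueError("cannot reach n_probes: no filler genes to extend")
        g = fillers[i % len(fillers)]
        if counts[g] < 4:
            counts[g] += 1
            fidelities[g].append(float(rng.uniform(0.3, 0.8)))
            total += 1
        i += 1
        if i > 8 * len(fillers) and total < cfg.n_probes:
            raise ValueError("cannot reach n_probes: filler genes saturated at 4 probes")
    probe_ids, probe_gene, probe_fid = [], {}, {}
    for g in genes:
        for k, f in enumerate(fidelities[g], start=1):
            pid = f"{g}_p{k}"
            probe_ids.append(pid)
            probe_gene[pid] = g
            probe_fid[pid] = f
    return genes, pd.Series(probe_gene, name="gene"), pd.Series(probe_fid, name="fidelity")


def _draw_annotation(cfg: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for entity in cfg.entities:
        n = cfg.entities[entity]
        mix = cfg.tissue_mix[entity]
        probs = np.array([mix.get(t, 0.0) for t in TISSUES])
        tissues = rng.choice(TISSUES, size=n, p=probs / probs.sum())
        sub_probs = cfg.subtypes.get(entity)
        if sub_probs:
            labels = list(sub_probs)
            weights = np.array([sub_probs[s] for s in labels], dtype=float)
            subtypes = rng.choice(labels, size=n, p=weights / weights.sum())
        else:
            subtypes = np.array(["NA"] * n)
        tf = cfg.transformed_fraction.get(entity, 0.0)
        transformed = rng.random(n) < tf
        series = rng.integers(0, cfg.series_per_entity, size=n)
        for i in range(n):
            if entity in NORMAL_ENTITIES:
                status = "normal"
            elif transformed[i]:
                status = "aggressive"
            elif entity in AGGRESSIVE_ENTITIES:
                status = "aggressive"
            else:
                status = "indolent"
            rows.append(
                {
                    "sample": f"{entity}_{i + 1:04d}",
                    "entity": entity,
                    "tissue": tissues[i],
                    "subtype": subtypes[i],
                    "status": status,
                    "transformed": bool(transformed[i]),
                    "series": f"{entity}_S{series[i] + 1}",
                }
            )
    ann = pd.DataFrame(rows).set_index("sample")
    return ann


def _effect(table: Mapping[str, Mapping[str, float]], gene: str, key: str) -> float:
    return float(table.get(gene, {}).get(key, 0.0))


def generate_dataset(
    cfg: SynthConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, GroundTruth]:
    """Generate the probe-level corpus with its annotation and ground truth.

    Returns ``(probe_matrix, annotation, probe_map, ground_truth)`` where
    `probe_matrix` has exactly ``cfg.n_probes`` rows (log2 scale) and one
    column per sample; `annotation` carries entity, tissue, subtype, status
    and series; `probe_map` maps probe id -> gene symbol. Fixing the seed
    fixes every output bit-for-bit.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genes, probe_map, probe_fid = _probe_layout(cfg, rng)
    ann = _draw_annotation(cfg, rng)
    n_samples = len(ann)

    # truncate to the post-summarization intensity floor/ceiling of log2 arrays
    baselines = pd.Series(
        np.clip(rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=len(genes)), 4.0, 12.0),
        index=genes,
    )
    all_series = sorted(ann["series"].unique())
    batch_offsets = {s: float(rng.normal(0.0, cfg.batch_sd)) for s in all_series}

    # effective entity per sample: transformed FL/MALT follow the DLBCL profile
    eff_entity = np.where(ann["transformed"].to_numpy(), "DLBCL", ann["entity"].to_numpy())

    gene_idx = {g: i for i, g in enumerate(genes)}
    effect_genes = [
        g
        for g in dict.fromkeys(
            list(cfg.entity_effects) + list(cfg.tissue_effects) + list(cfg.subtype_effects)
        )
        if g in gene_idx
    ]
    shift = np.zeros((len(genes), n_samples))
    for j, (sample, row) in enumerate(ann.iterrows()):
        e, t, s = eff_entity[j], row["tissue"], row["subtype"]
        for gene in effect_genes:
            shift[gene_idx[gene], j] = (
                _effect(cfg.entity_effects, gene, e)
                + _effect(cfg.tissue_effects, gene, t)
                + _effect(cfg.subtype_effects, gene, s)
            )
        shift[:, j] += batch_offsets[row["series"]]

    latent = (
        baselines.to_numpy()[:, None]
        + shift
        + rng.normal(0.0, cfg.noise_sd, size=(len(genes), n_samples))
    )
    latent_df = pd.DataFrame(latent, index=genes, columns=ann.index)

    fid = probe_fid.to_numpy()[:, None]
    gene_rows = latent_df.loc[probe_map.to_numpy()].to_numpy()
    noise_channel = (
        baselines.loc[probe_map.to_numpy()].to_numpy()[:, None]
        + rng.normal(0.0, cfg.probe_noise_sd, size=(len(probe_map), n_samples))
    )
    probe_values = fid * gene_rows + (1.0 - fid) * noise_channel
    probe_matrix = pd.DataFrame(probe_values, index=probe_map.index, columns=ann.index)
    probe_matrix.index.name = "probe"

    implied = implied_orr(cfg, latent_df, ann)
    gt = GroundTruth(
        latent=latent_df,
        probe_fidelity=probe_fid,
        baselines=baselines,
        batch_offsets=batch_offsets,
        entity_effects=cfg.entity_effects,
        tissue_effects=cfg.tissue_effects,
        planted_ratio=cfg.planted_ratio,
        implied_orr=implied,
    )
    return probe_matrix, ann, probe_map, gt


def implied_orr(
    cfg: SynthConfig, latent: pd.DataFrame, annotation: pd.DataFrame
) -> dict[str, float]:
    """Entity-level ORR implied by the linear link on the planted-ratio median.

    ``ORR(e) = clip(intercept + slope * median ratio(e), 0, 100)``. When no
    intercept is configured it is set so the across-entity mean ORR is 50%,
    keeping values inside the truncation range for moderate slopes. With
    ``orr_link_slope = 0`` there is no planted relation: entity ORR values
    are drawn uniformly on [10, 90], independent of expression, so that
    null-link correlations remain well defined.
    """
    malignant = [e for e in cfg.entities if e not in NORMAL_ENTITIES]
    if cfg.orr_link_slope == 0:
        rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 7]))
        return {e: float(rng.uniform(10.0, 90.0)) for e in malignant}
    scores = ratio_score(latent, cfg.planted_ratio)
    med = {
        e: float(scores[annotation["entity"] == e].median()) for e in malignant
    }
    if cfg.orr_link_intercept is None:
        intercept = 50.0 - cfg.orr_link_slope * float(np.mean(list(med.values())))
    else:
        intercept = cfg.orr_link_intercept
    return {
        e: float(np.clip(intercept + cfg.orr_link_slope * m, 0.0, 100.0))
        for e, m in med.items()
    }


def probe_layout(cfg: SynthConfig) -> tuple[pd.Series, pd.Series]:
    """The probe->gene map and per-probe fidelities a config implies.

    Identical to the layout used by `generate_dataset` and
    `generate_cellline_panel` for the same seed.
    """
    cfg.validate()
    _, probe_map, probe_fid = _probe_layout(cfg, np.random.default_rng(cfg.seed))
    return probe_map, probe_fid


def generate_cellline_panel(cfg: SynthConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Matched cell-line panel: probe-level GEP and gene-level RNA-seq stand-in.

    Both matrices cover the same cell lines (default n = 19). The gene-level
    matrix is the latent signal on a log2(x+1)-like scale; probe values mix
    the latent signal with independent noise according to probe fidelity.
    """
    cfg.validate()
    if cfg.n_celllines < 3:
        raise ValueError("need at least 3 cell lines")
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 1]))
    genes, probe_map, probe_fid = _probe_layout(cfg, np.random.default_rng(cfg.seed))
    lines = [f"CL{i + 1:02d}" for i in range(cfg.n_celllines)]
    baselines = np.clip(
        rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=len(genes)), 4.0, 12.0
    )
    latent = baselines[:, None] + rng.normal(
        0.0, cfg.cellline_sd, size=(len(genes), cfg.n_celllines)
    )
    rnaseq = pd.DataFrame(latent, index=genes, columns=lines)
    fid = probe_fid.to_numpy()[:, None]
    gene_rows = rnaseq.loc[probe_map.to_numpy()].to_numpy()
    base_ser = pd.Series(baselines, index=genes)
    noise = base_ser.loc[probe_map.to_numpy()].to_numpy()[:, None] + rng.normal(
        0.0, cfg.cellline_sd, size=(len(probe_map), cfg.n_celllines)
    )
    gep = pd.DataFrame(
        fid * gene_rows + (1.0 - fid) * noise, index=probe_map.index, columns=lines
    )
    gep.index.name = "probe"
    rnaseq.index.name = "gene"
    return gep, rnaseq


def default_orr_table() -> dict[str, float]:
    """Published venetoclax-monotherapy overall response rates (percent).

    Entities without reported trial data (BPLL, HCL, BL, SMZL, MALT) carry
    no value and are scored but excluded from correlations.
    """
    return {"CLL": 79.0, "MCL": 75.0, "FL": 38.0, "DLBCL": 18.0, "MM": 21.0}
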