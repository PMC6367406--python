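"""Synthetic TNBC cohort generator.

Emulates the statistical structure the downstream analysis assumes: gene
modules with a single shared latent factor (equicorrelation at loading
``rho``), four planted cellular subtypes (LAR, basal, CLDN-low, CLDN-high)
whose identities live in role-specific module mean shifts, an independent
binary immune layer, additive per-batch shifts, and label-dependent
exponential relapse-free survival with censoring.

The model for gene ``g`` in module ``M`` and sample ``i`` is (log2 units)

    x_gi = baseline + shift_M(subtype_i, immune_i)
           + noise_sd * ( sqrt(rho) * z_i^M  +  sqrt(1 - rho) * eps_gi )
           + batch_shift(batch_i)

with ``z`` and ``eps`` independent standard normals.  Noise genes carry no
shift and no latent factor.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd

from .io import ClinicalTable, ExpressionMatrix, GeneSetCollection, MarkerConfig

__all__ = [
    "SUBTYPES",
    "IMMUNE_LABELS",
    "ModuleSpec",
    "CohortSpec",
    "generate_expression",
    "generate_survival",
    "default_cohort_spec",
    "default_markers",
    "default_gene_sets",
]

SUBTYPES = ("LAR", "basal", "CLDN-low", "CLDN-high")
IMMUNE_LABELS = ("IM+", "IM-")


@dataclasses.dataclass
class ModuleSpec:
    """One co-expression module (a planted functional node).

    ``mean_shift`` maps ``(subtype, immune_label)`` to a log2-unit shift;
    missing cells default to 0.
    """

    module_id: str
    role: str  # luminal | basal | claudin | immune | other
    genes: list[str]
    latent_loading: float = 0.8
    mean_shift: dict[tuple[str, str], float] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.latent_loading < 1.0:
            raise ValueError(f"module {self.module_id}: latent_loading must be in [0, 1)")
        if len(self.genes) == 0:
            raise ValueError(f"module {self.module_id}: empty gene list")

    def shift(self, subtype: str, immune: str) -> float:
        return self.mean_shift.get((subtype, immune), 0.0)


def _additive_shift(subtype_shift: Mapping[str, float], immune_shift: float = 0.0) -> dict:
    """Build a (subtype, immune) shift table from additive components."""
    table = {}
    for s in SUBTYPES:
        for m in IMMUNE_LABELS:
            table[(s, m)] = subtype_shift.get(s, 0.0) + (immune_shift if m == "IM+" else 0.0)
    return table


@dataclasses.dataclass
class CohortSpec:
    """Full description of a synthetic cohort."""

    n_samples: dict[str, int]  # per cellular subtype
    immune_positive_fraction: dict[str, float]  # per cellular subtype
    modules: list[ModuleSpec]
    n_noise_genes: int = 500
    batch_count: int = 1
    batch_shift: float = 0.0  # log2 units between adjacent batches
    noise_sd: float = 0.5  # log2 units
    baseline_log2: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        for s, n in self.n_samples.items():
            if s not in SUBTYPES:
                raise ValueError(f"unknown subtype {s!r}")
            if n < 0:
                raise ValueError("subtype counts must be >= 0")
        for s, f in self.immune_positive_fraction.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError("immune_positive_fraction must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        all_genes: set[str] = set()
        for mod in self.modules:
            overlap = all_genes.intersection(mod.genes)
            if overlap:
                raise ValueError(f"gene(s) {sorted(overlap)} appear in more than one module")
            all_genes.update(mod.genes)

    @property
    def total_samples(self) -> int:
        return sum(self.n_samples.values())


def generate_expression(
    spec: CohortSpec, output_scale: str = "log2"
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate a cohort; returns (expression, truth table).

    ``output_scale='raw'`` exponentiates (2**x) so the matrix can exercise
    the full preprocessing chain from raw intensities.  The truth table has
    columns sample_id, subtype, immune, batch.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.total_samples
    if n == 0:
        raise ValueError("cohort has no samples")

    # --- sample labels ---------------------------------------------------
    subtypes: list[str] = []
    immune: list[str] = []
    for s in SUBTYPES:
        ns = spec.n_samples.get(s, 0)
        frac = spec.immune_positive_fraction.get(s, 0.5)
        n_pos = int(round(frac * ns))
        flags = np.array(["IM+"] * n_pos + ["IM-"] * (ns - n_pos), dtype=object)
        rng.shuffle(flags)
        subtypes.extend([s] * ns)
        immune.extend(flags.tolist())
    order = rng.permutation(n)
    subtypes = [subtypes[i] for i in order]
    immune = [immune[i] for i in order]
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    batches = [f"B{(i % max(spec.batch_count, 1)) + 1}" for i in range(n)]
    # centered so the global mean is batch-free
    batch_levels = sorted(set(batches))
    offsets = {
        b: spec.batch_shift * (k - (len(batch_levels) - 1) / 2.0)
        for k, b in enumerate(batch_levels)
    }

    # --- expression ------------------------------------------------------
    gene_ids: list[str] = []
    blocks: list[np.ndarray] = []
    for mod in spec.modules:
        p = len(mod.genes)
        rho = mod.latent_loading
        z = rng.standard_normal(n)  # shared latent factor, one per module
        eps = rng.standard_normal((p, n))
        signal = spec.noise_sd * (np.sqrt(rho) * z[None, :] + np.sqrt(1.0 - rho) * eps)
        shift = np.array([mod.shift(s, m) for s, m in zip(subtypes, immune)])
        blocks.append(signal + shift[None, :])
        gene_ids.extend(mod.genes)
    if spec.n_noise_genes:
        noise = spec.noise_sd * rng.standard_normal((spec.n_noise_genes, n))
        blocks.append(noise)
        gene_ids.extend(f"NOISE{i + 1:04d}" for i in range(spec.n_noise_genes))

    values = np.vstack(blocks) + spec.baseline_log2
    values += np.array([offsets[b] for b in batches])[None, :]

    scale_flag = "log2"
    if output_scale == "raw":
        values = np.exp2(values)
        scale_flag = "raw"
    elif output_scale != "log2":
        raise ValueError("output_scale must be 'log2' or 'raw'")

    expr = ExpressionMatrix(
        probe_ids=list(gene_ids),
        gene_ids=list(gene_ids),
        sample_ids=sample_ids,
        values=values,
        batch=batches if spec.batch_count > 1 else None,
        scale_flag=scale_flag,
    )
    truth = pd.DataFrame(
        {"sample_id": sample_ids, "subtype": subtypes, "immune": immune, "batch": batches}
    )
    return expr, truth


def generate_survival(
    truth: pd.DataFrame,
    hazard_map: Mapping[str, float],
    censor_rate: float = 0.0,
    horizon_months: float = 120.0,
    seed: int = 0,
    label_column: str = "subtype",
) -> ClinicalTable:
    """Exponential relapse-free survival with independent exponential and
    administrative censoring.

    Event times are Exp(rate) per label; an event is recorded iff the event
    time precedes both the censoring time and the follow-up horizon.
    """
    rng = np.random.default_rng(seed)
    labels = truth[label_column].tolist()
    missing = sorted(set(labels) - set(hazard_map))
    if missing:
        raise ValueError(f"hazard_map missing labels: {missing}")
    for lab, rate in hazard_map.items():
        if rate <= 0:
            raise ValueError(f"hazard rate for {lab!r} must be > 0")
    if horizon_months < 0:
        raise ValueError("horizon_months must be >= 0")

    n = len(labels)
    rates = np.array([hazard_map[l] for l in labels])
    event_time = rng.exponential(1.0 / rates)
    if censor_rate > 0:
        censor_time = rng.exponential(1.0 / censor_rate, size=n)
    else:
        censor_time = np.full(n, np.inf)
    limit = np.minimum(censor_time, horizon_months)
    observed = np.minimum(event_time, limit)
    event = (event_time <= limit).astype(int)

    frame = pd.DataFrame(
        {
            "sample_id": truth["sample_id"].tolist(),
            "rfs_time": observed,
            "event": event,
            "size": np.nan,
            "grade": np.nan,
            "nodal": np.nan,
            "adjuvant_chemo": np.nan,
            "path_response": np.nan,
        }
    )
    return ClinicalTable(frame)


# ---------------------------------------------------------------------------
# Default cohort: 26 modules mirroring the functional-node structure of a
# TNBC co-expression network (1 claudin node, 6 luminal, 5 basal, 4 immune,
# 10 unshifted "other" modules).
# ---------------------------------------------------------------------------

_N_LUMINAL, _N_BASAL, _N_IMMUNE, _N_OTHER = 6, 5, 4, 10
_MODULE_SIZE = 15
_CLAUDIN_SIZE = 34


def _module_genes(prefix: str, idx: int, size: int) -> list[str]:
    return [f"{prefix}{idx}_G{j + 1:02d}" for j in range(size)]


def default_cohort_spec(
    n_total: int = 400,
    shift: float = 1.0,
    rho: float = 0.8,
    noise_sd: float = 0.5,
    n_noise_genes: int = 500,
    batch_count: int = 2,
    batch_shift: float = 0.3,
    seed: int = 0,
) -> CohortSpec:
    """The default study conditions: 26 planted modules, four subtypes in
    roughly the clinical proportions (18/63/11/8 %), immune layer drawn
    independently at 50%, 1.0 log2-unit role shifts."""
    fractions = {"LAR": 0.18, "basal": 0.63, "CLDN-low": 0.11, "CLDN-high": 0.08}
    n_samples = {s: int(round(f * n_total)) for s, f in fractions.items()}
    n_samples["basal"] += n_total - sum(n_samples.values())  # absorb rounding

    modules: list[ModuleSpec] = []
    # claudin node: high in every epithelial-differentiated subtype, low only
    # in CLDN-low tumors
    claudin_genes = ["CLDN3", "CLDN4", "CLDN7"] + _module_genes("CLD", 1, _CLAUDIN_SIZE - 3)
    modules.append(
        ModuleSpec(
            "node_claudin",
            "claudin",
            claudin_genes,
            rho,
            _additive_shift({"LAR": shift, "basal": shift, "CLDN-high": shift}),
        )
    )
    for i in range(_N_LUMINAL):
        modules.append(
            ModuleSpec(
                f"node_luminal_{i + 1}",
                "luminal",
                _module_genes("LUM", i + 1, _MODULE_SIZE),
                rho,
                _additive_shift({"LAR": shift}),
            )
        )
    for i in range(_N_BASAL):
        modules.append(
            ModuleSpec(
                f"node_basal_{i + 1}",
                "basal",
                _module_genes("BAS", i + 1, _MODULE_SIZE),
                rho,
                _additive_shift({"basal": shift}),
            )
        )
    for i in range(_N_IMMUNE):
        modules.append(
            ModuleSpec(
                f"node_immune_{i + 1}",
                "immune",
                _module_genes("IMM", i + 1, _MODULE_SIZE),
                rho,
                _additive_shift({}, immune_shift=shift),
            )
        )
    for i in range(_N_OTHER):
        modules.append(
            ModuleSpec(
                f"node_other_{i + 1}",
                "other",
                _module_genes("OTH", i + 1, _MODULE_SIZE),
                rho,
            )
        )

    return CohortSpec(
        n_samples=n_samples,
        immune_positive_fraction={s: 0.5 for s in SUBTYPES},
        modules=modules,
        n_noise_genes=n_noise_genes,
        batch_count=batch_count,
        batch_shift=batch_shift,
        noise_sd=noise_sd,
        seed=seed,
    )


def cohort_spec_from_dict(data: Mapping) -> CohortSpec:
    """Build a CohortSpec from a plain mapping (YAML/JSON config).

    Module entries may give either an explicit ``mean_shift`` table (keys
    "subtype|immune") or additive ``subtype_shift`` / ``immune_shift``
    components.
    """
    modules = []
    for entry in data.get("modules", []):
        if "mean_shift" in entry:
            shift = {tuple(k.split("|")): float(v) for k, v in entry["mean_shift"].items()}
        else:
            shift = _additive_shift(
                entry.get("subtype_shift", {}), float(entry.get("immune_shift", 0.0))
            )
        modules.append(
            ModuleSpec(
                module_id=str(entry["module_id"]),
                role=str(entry.get("role", "other")),
                genes=[str(g) for g in entry["genes"]],
                latent_loading=float(entry.get("latent_loading", 0.8)),
                mean_shift=shift,
            )
        )
    return CohortSpec(
        n_samples={str(k): int(v) for k, v in data["n_samples"].items()},
        immune_positive_fraction={
            str(k): float(v) for k, v in data.get("immune_positive_fraction", {}).items()
        },
        modules=modules,
        n_noise_genes=int(data.get("n_noise_genes", 500)),
        batch_count=int(data.get("batch_count", 1)),
        batch_shift=float(data.get("batch_shift", 0.0)),
        noise_sd=float(data.get("noise_sd", 0.5)),
        baseline_log2=float(data.get("baseline_log2", 8.0)),
        seed=int(data.get("seed", 0)),
    )


def cohort_spec_to_dict(spec: CohortSpec) -> dict:
    """Inverse of :func:`cohort_spec_from_dict` (explicit shift tables)."""
    return {
        "n_samples": dict(spec.n_samples),
        "immune_positive_fraction": dict(spec.immune_positive_fraction),
        "modules": [
            {
                "module_id": mod.module_id,
                "role": mod.role,
                "genes": list(mod.genes),
                "latent_loading": mod.latent_loading,
                "mean_shift": {f"{s}|{m}": v for (s, m), v in mod.mean_shift.items() if v != 0.0},
            }
            for mod in spec.modules
        ],
        "n_noise_genes": spec.n_noise_genes,
        "batch_count": spec.batch_count,
        "batch_shift": spec.batch_shift,
        "noise_sd": spec.noise_sd,
        "baseline_log2": spec.baseline_log2,
        "seed": spec.seed,
    }


def default_markers(spec: CohortSpec) -> MarkerConfig:
    """Marker lists: claudin markers plus the two leading genes of every
    shifted module, keyed by role."""
    markers: dict[str, list[str]] = {"claudin": ["CLDN3", "CLDN4", "CLDN7"]}
    for mod in spec.modules:
        if mod.role in ("luminal", "basal", "immune"):
            markers.setdefault(mod.role, []).extend(mod.genes[:2])
    return MarkerConfig(markers)


_ROLE_TERMS = {
    "claudin": "tight junction",
    "luminal": "hormone receptor signaling",
    "basal": "keratinization",
    "immune": "immune response",
    "other": "generic process",
}


def default_gene_sets(spec: CohortSpec) -> GeneSetCollection:
    """One annotation term per planted module (role-flavoured names)."""
    term_ids = [f"TERM:{mod.module_id}" for mod in spec.modules]
    term_names = [f"{_ROLE_TERMS[mod.role]} ({mod.module_id})" for mod in spec.modules]
    genes = [list(mod.genes) for mod in spec.modules]
    return GeneSetCollection(term_ids, term_names, genes, source="synthetic")
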