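"""Dirichlet-multinomial simulator for per-cell splice-junction counts.

Cells of labelled types emit junctional reads at a gene's anchor splice
sites; each read picks a partner site from the cell's usage vector, which is
a Dirichlet perturbation of the cell type's multinomial usage vector.  Total
reads per cell-gene follow a negative binomial (droplet-style overdispersed
depth).  Optional blocks plant pseudotime-drifting usage (a logistic blend
between two vectors) and hidden within-type subpopulations (a cell type that
is a mixture of two usage vectors).  Every planted signal is recorded in a
:class:`PlantedTruth` object so downstream recovery can be scored without
re-reading the configuration.

Defaults (depth mean 10, dispersion 2, Dirichlet concentration 100) emulate
sparse droplet data with mild within-type usage heterogeneity, under which the
SpliZ null is approximately standard normal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CellTypeSpec",
    "AnchorSpec",
    "GeneSpec",
    "TrajectorySpec",
    "SubpopulationSpec",
    "SimulationConfig",
    "PlantedTruth",
    "simulate_dataset",
    "simulate_null_dataset",
    "simulate_trajectory_dataset",
    "make_null_config",
    "make_differential_config",
    "make_site_recovery_config",
    "make_subpopulation_config",
    "make_trajectory_config",
]


@dataclass(frozen=True)
class CellTypeSpec:
    name: str
    tissue: str
    compartment: str
    n_cells: int


@dataclass(frozen=True)
class AnchorSpec:
    """An anchor splice site and its partner sites (order defines the usage vector)."""

    position: int
    partner_positions: tuple[int, ...]
    role: str = "donor"


@dataclass
class GeneSpec:
    name: str
    chrom: str
    strand: str
    anchors: tuple[AnchorSpec, ...]
    # cell-type name (or "*" default) -> per-anchor usage probability vectors
    usage: dict[str, tuple[tuple[float, ...], ...]]

    def usage_for(self, cell_type: str) -> tuple[tuple[float, ...], ...]:
        if cell_type in self.usage:
            return self.usage[cell_type]
        return self.usage["*"]


@dataclass(frozen=True)
class TrajectorySpec:
    """Usage at one anchor drifts from ``start`` to ``end`` as a logistic function of pseudotime."""

    gene: str
    anchor_index: int
    start: tuple[float, ...]
    end: tuple[float, ...]
    steepness: float = 8.0


@dataclass(frozen=True)
class SubpopulationSpec:
    """One cell type is a hidden mixture of two usage vectors at one anchor."""

    cell_type: str
    gene: str
    anchor_index: int
    usage_a: tuple[float, ...]
    usage_b: tuple[float, ...]
    proportion_a: float = 0.5


@dataclass
class SimulationConfig:
    seed: int
    cell_types: tuple[CellTypeSpec, ...]
    genes: tuple[GeneSpec, ...]
    dirichlet_concentration: float = 100.0
    depth_mean: float = 10.0
    depth_dispersion: float = 2.0
    trajectory: tuple[TrajectorySpec, ...] = ()
    subpopulations: tuple[SubpopulationSpec, ...] = ()

    def validate(self) -> None:
        if self.dirichlet_concentration <= 0:
            raise ValueError("dirichlet_concentration must be > 0")
        if self.depth_mean <= 0 or self.depth_dispersion <= 0:
            raise ValueError("depth model parameters must be > 0")
        for gene in self.genes:
            if not gene.anchors:
                raise ValueError(f"gene {gene.name}: no anchors")
            for i, anchor in enumerate(gene.anchors):
                if len(anchor.partner_positions) < 1:
                    raise ValueError(f"gene {gene.name} anchor {anchor.position}: zero partners")
                offsets = [abs(p - anchor.position) for p in anchor.partner_positions]
                if len(set(anchor.partner_positions)) != len(anchor.partner_positions):
                    raise ValueError(f"gene {gene.name} anchor {anchor.position}: duplicate partners")
                if len(set(offsets)) != len(offsets):
                    raise ValueError(f"gene {gene.name} anchor {anchor.position}: offsets not distinct")
                for vectors in gene.usage.values():
                    vec = vectors[i]
                    if len(vec) != len(anchor.partner_positions):
                        raise ValueError(f"gene {gene.name} anchor {anchor.position}: usage length mismatch")
                    if abs(sum(vec) - 1.0) > 1e-8:
                        raise ValueError(f"gene {gene.name} anchor {anchor.position}: usage does not sum to 1")
            if "*" not in gene.usage and not all(ct.name in gene.usage for ct in self.cell_types):
                raise ValueError(f"gene {gene.name}: usage missing for some cell types and no '*' default")

    # --- (de)serialization for the YAML-driven CLI -------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        def _tup(vectors):
            return tuple(tuple(float(x) for x in v) for v in vectors)

        genes = tuple(
            GeneSpec(
                name=g["name"],
                chrom=g.get("chrom", "chr1"),
                strand=g.get("strand", "+"),
                anchors=tuple(
                    AnchorSpec(
                        position=int(a["position"]),
                        partner_positions=tuple(int(p) for p in a["partner_positions"]),
                        role=a.get("role", "donor"),
                    )
                    for a in g["anchors"]
                ),
                usage={k: _tup(v) for k, v in g["usage"].items()},
            )
            for g in d["genes"]
        )
        return cls(
            seed=int(d["seed"]),
            cell_types=tuple(CellTypeSpec(**ct) for ct in d["cell_types"]),
            genes=genes,
            dirichlet_concentration=float(d.get("dirichlet_concentration", 100.0)),
            depth_mean=float(d.get("depth_mean", 10.0)),
            depth_dispersion=float(d.get("depth_dispersion", 2.0)),
            trajectory=tuple(
                TrajectorySpec(
                    gene=t["gene"],
                    anchor_index=int(t["anchor_index"]),
                    start=tuple(float(x) for x in t["start"]),
                    end=tuple(float(x) for x in t["end"]),
                    steepness=float(t.get("steepness", 8.0)),
                )
                for t in d.get("trajectory", ())
            ),
            subpopulations=tuple(
                SubpopulationSpec(
                    cell_type=s["cell_type"],
                    gene=s["gene"],
                    anchor_index=int(s["anchor_index"]),
                    usage_a=tuple(float(x) for x in s["usage_a"]),
                    usage_b=tuple(float(x) for x in s["usage_b"]),
                    proportion_a=float(s.get("proportion_a", 0.5)),
                )
                for s in d.get("subpopulations", ())
            ),
        )


@dataclass
class PlantedTruth:
    """The simulator's record of every planted signal, for recovery scoring."""

    # gene -> {"differential": bool, "up_cell_type": str|None}
    differential: dict[str, dict] = field(default_factory=dict)
    # gene -> list of planted variable anchor positions
    variable_anchors: dict[str, list[int]] = field(default_factory=dict)
    # cell_id -> subpopulation component (0 = usage_a, 1 = usage_b), planted cells only
    subpopulation: dict[str, int] = field(default_factory=dict)
    # gene -> expected sign of the SpliZ-pseudotime correlation (+1/-1)
    trajectory: dict[str, int] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PlantedTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            differential=d["differential"],
            variable_anchors={k: list(v) for k, v in d["variable_anchors"].items()},
            subpopulation={k: int(v) for k, v in d["subpopulation"].items()},
            trajectory={k: int(v) for k, v in d["trajectory"].items()},
        )


# ---------------------------------------------------------------------------
# Generation engine
# ---------------------------------------------------------------------------


def _vector_multinomial(rng: np.random.Generator, n: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Row-wise multinomial draws via conditional binomials (p varies per row)."""
    m, k = p.shape
    out = np.zeros((m, k), dtype=np.int64)
    remaining = n.astype(np.int64).copy()
    rem_p = np.ones(m)
    for j in range(k - 1):
        with np.errstate(divide="ignore", invalid="ignore"):
            pj = np.where(rem_p > 1e-12, np.clip(p[:, j] / rem_p, 0.0, 1.0), 0.0)
        out[:, j] = rng.binomial(remaining, pj)
        remaining -= out[:, j]
        rem_p = rem_p - p[:, j]
    out[:, -1] = remaining
    return out


def _dirichlet_rows(rng: np.random.Generator, base: np.ndarray, concentration: float) -> np.ndarray:
    """Dirichlet(concentration * base_row) draw for every row; inf concentration = no noise."""
    if np.isinf(concentration):
        return base
    shape = concentration * base
    g = rng.gamma(np.maximum(shape, 0.0))
    g[shape <= 0.0] = 0.0
    totals = g.sum(axis=1, keepdims=True)
    bad = totals[:, 0] <= 0.0
    if bad.any():  # astronomically unlikely gamma underflow: fall back to the mean
        g[bad] = base[bad]
        totals = g.sum(axis=1, keepdims=True)
    return g / totals


def _logistic_blend(t: np.ndarray, start: np.ndarray, end: np.ndarray, steepness: float) -> np.ndarray:
    w = 1.0 / (1.0 + np.exp(-steepness * (t - 0.5)))
    return (1.0 - w)[:, None] * start[None, :] + w[:, None] * end[None, :]


def _make_annotations(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for ct in config.cell_types:
        for i in range(ct.n_cells):
            rows.append(
                {
                    "cell_id": f"{ct.name}_c{i:04d}",
                    "individual": "ind1",
                    "tissue": ct.tissue,
                    "compartment": ct.compartment,
                    "cell_type": ct.name,
                }
            )
    return pd.DataFrame(rows)


def _rank_of_partners(anchor: AnchorSpec) -> np.ndarray:
    dist = np.abs(np.asarray(anchor.partner_positions) - anchor.position)
    order = np.lexsort((anchor.partner_positions, dist))
    ranks = np.empty(len(order), dtype=float)
    ranks[order] = np.arange(1, len(order) + 1)
    return ranks


def _planted_truth_static(config: SimulationConfig) -> PlantedTruth:
    truth = PlantedTruth()
    type_names = [ct.name for ct in config.cell_types]
    for gene in config.genes:
        per_type = {ct: gene.usage_for(ct) for ct in type_names}
        variable: list[int] = []
        for i, anchor in enumerate(gene.anchors):
            vecs = {tuple(per_type[ct][i]) for ct in type_names}
            if len(vecs) > 1:
                variable.append(anchor.position)
        is_diff = bool(variable)
        up_type = None
        if is_diff:
            # expected mean partner rank per type, averaged over anchors
            ranks = [_rank_of_partners(a) for a in gene.anchors]
            mean_rank = {
                ct: float(np.mean([np.dot(ranks[i], per_type[ct][i]) for i in range(len(gene.anchors))]))
                for ct in type_names
            }
            pooled = float(np.mean(list(mean_rank.values())))
            up_type = max(type_names, key=lambda ct: (abs(mean_rank[ct] - pooled), ct))
            up_type_sign = 1 if mean_rank[up_type] >= pooled else -1
            truth.differential[gene.name] = {
                "differential": True,
                "up_cell_type": up_type,
                "direction": up_type_sign,
            }
        else:
            truth.differential[gene.name] = {"differential": False, "up_cell_type": None, "direction": 0}
        truth.variable_anchors[gene.name] = variable
    for spec in config.trajectory:
        gene = next(g for g in config.genes if g.name == spec.gene)
        ranks = _rank_of_partners(gene.anchors[spec.anchor_index])
        drift = float(np.dot(ranks, spec.end) - np.dot(ranks, spec.start))
        truth.trajectory[spec.gene] = int(np.sign(drift)) if drift else 0
        if drift:
            truth.differential.setdefault(spec.gene, {})
            truth.variable_anchors.setdefault(spec.gene, [])
            pos = gene.anchors[spec.anchor_index].position
            if pos not in truth.variable_anchors[spec.gene]:
                truth.variable_anchors[spec.gene].append(pos)
    return truth


def _simulate(config: SimulationConfig, with_pseudotime: bool) -> tuple[pd.DataFrame, pd.DataFrame, PlantedTruth]:
    config.validate()
    rng = np.random.default_rng(config.seed)
    ann = _make_annotations(config)
    n_cells = len(ann)
    cell_ids = ann["cell_id"].to_numpy()
    cell_type_of = ann["cell_type"].to_numpy()
    truth = _planted_truth_static(config)

    pseudotime = None
    if with_pseudotime:
        pseudotime = rng.uniform(0.0, 1.0, size=n_cells)
        ann = ann.assign(pseudotime=pseudotime)
    elif config.trajectory:
        raise ValueError("config has trajectory blocks; use simulate_trajectory_dataset")

    # hidden subpopulation memberships, drawn once per planted spec
    membership: dict[tuple[str, str], np.ndarray] = {}
    for spec in config.subpopulations:
        mask = cell_type_of == spec.cell_type
        comp = (rng.uniform(size=int(mask.sum())) >= spec.proportion_a).astype(int)  # 0=a, 1=b
        membership[(spec.cell_type, spec.gene)] = comp
        for cid, c in zip(cell_ids[mask], comp):
            truth.subpopulation[str(cid)] = int(c)
        if tuple(spec.usage_a) != tuple(spec.usage_b):
            gene = next(g for g in config.genes if g.name == spec.gene)
            pos = gene.anchors[spec.anchor_index].position
            truth.variable_anchors.setdefault(spec.gene, [])
            if pos not in truth.variable_anchors[spec.gene]:
                truth.variable_anchors[spec.gene].append(pos)

    traj_by_gene: dict[str, dict[int, TrajectorySpec]] = {}
    for spec in config.trajectory:
        traj_by_gene.setdefault(spec.gene, {})[spec.anchor_index] = spec

    disp = config.depth_dispersion
    p_nb = disp / (disp + config.depth_mean)

    records: list[pd.DataFrame] = []
    for gene in config.genes:
        depth = rng.negative_binomial(disp, p_nb, size=n_cells)
        n_anchors = len(gene.anchors)
        anchor_weights = np.full((n_cells, n_anchors), 1.0 / n_anchors)
        anchor_counts = _vector_multinomial(rng, depth, anchor_weights)
        for i, anchor in enumerate(gene.anchors):
            k = len(anchor.partner_positions)
            base = np.empty((n_cells, k))
            for ct in config.cell_types:
                mask = cell_type_of == ct.name
                base[mask] = np.asarray(gene.usage_for(ct.name)[i])
            if (traj := traj_by_gene.get(gene.name, {}).get(i)) is not None:
                base = _logistic_blend(pseudotime, np.asarray(traj.start), np.asarray(traj.end), traj.steepness)
            for spec in config.subpopulations:
                if spec.gene == gene.name and spec.anchor_index == i:
                    mask = cell_type_of == spec.cell_type
                    comp = membership[(spec.cell_type, spec.gene)]
                    vecs = np.where(comp[:, None] == 0, np.asarray(spec.usage_a), np.asarray(spec.usage_b))
                    base[mask] = vecs
            p_cells = _dirichlet_rows(rng, base, config.dirichlet_concentration)
            partner_counts = _vector_multinomial(rng, anchor_counts[:, i], p_cells)
            for j, partner in enumerate(anchor.partner_positions):
                nz = np.flatnonzero(partner_counts[:, j])
                if nz.size == 0:
                    continue
                donor = anchor.position if anchor.role == "donor" else partner
                acceptor = partner if anchor.role == "donor" else anchor.position
                records.append(
                    pd.DataFrame(
                        {
                            "cell_id": cell_ids[nz],
                            "gene": gene.name,
                            "chrom": gene.chrom,
                            "strand": gene.strand,
                            "donor_pos": donor,
                            "acceptor_pos": acceptor,
                            "count": partner_counts[nz, j],
                        }
                    )
                )
    if records:
        counts = pd.concat(records, ignore_index=True)
        counts = counts.sort_values(
            ["gene", "cell_id", "donor_pos", "acceptor_pos"], kind="mergesort"
        ).reset_index(drop=True)
    else:
        counts = pd.DataFrame(
            columns=["cell_id", "gene", "chrom", "strand", "donor_pos", "acceptor_pos", "count"]
        )
    return counts, ann, truth


def simulate_dataset(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame, PlantedTruth]:
    """Draw a junction-count table, cell annotations and planted truth. Deterministic per seed."""
    return _simulate(config, with_pseudotime=False)


def null_config(config: SimulationConfig) -> SimulationConfig:
    """Copy of a config in which all cell types share one usage vector per anchor."""
    genes = tuple(
        GeneSpec(
            name=g.name,
            chrom=g.chrom,
            strand=g.strand,
            anchors=g.anchors,
            usage={"*": g.usage.get("*", g.usage_for(config.cell_types[0].name))},
        )
        for g in config.genes
    )
    return SimulationConfig(
        seed=config.seed,
        cell_types=config.cell_types,
        genes=genes,
        dirichlet_concentration=config.dirichlet_concentration,
        depth_mean=config.depth_mean,
        depth_dispersion=config.depth_dispersion,
    )


def simulate_null_dataset(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame, PlantedTruth]:
    """Like :func:`simulate_dataset` but with exchangeable cell types (shared usage)."""
    return _simulate(null_config(config), with_pseudotime=False)


def simulate_trajectory_dataset(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame, PlantedTruth]:
    """Like :func:`simulate_dataset` with uniform-[0,1] pseudotime driving trajectory blocks."""
    return _simulate(config, with_pseudotime=True)


# ---------------------------------------------------------------------------
# Study-condition config builders
# ---------------------------------------------------------------------------

GENE_SPACING = 1_000_000
ANCHOR_SPACING = 10_000
PARTNER_STEP = 1_000


def _gene_layout(index: int, n_anchors: int, n_partners: int) -> tuple[tuple[AnchorSpec, ...], str]:
    """Deterministic star-topology gene: donor anchors, partners at increasing offsets."""
    base = 1_000_000 + index * GENE_SPACING
    anchors = tuple(
        AnchorSpec(
            position=base + a * ANCHOR_SPACING,
            partner_positions=tuple(base + a * ANCHOR_SPACING + (k + 1) * PARTNER_STEP for k in range(n_partners)),
        )
        for a in range(n_anchors)
    )
    return anchors, f"G{index:04d}"


def default_cell_types(n_cells_per_type: int = 50) -> tuple[CellTypeSpec, ...]:
    """Four cell types in two tissue+compartment contexts (two types per context)."""
    return (
        CellTypeSpec("typeA", "lung", "immune", n_cells_per_type),
        CellTypeSpec("typeB", "lung", "immune", n_cells_per_type),
        CellTypeSpec("typeC", "muscle", "stromal", n_cells_per_type),
        CellTypeSpec("typeD", "muscle", "stromal", n_cells_per_type),
    )


def _two_partner_usage(f_far: float) -> tuple[float, float]:
    # partner order is (near, far); f_far is the usage of the farther partner
    return (1.0 - f_far, f_far)


def make_null_config(
    n_genes: int = 500,
    n_cells_per_type: int = 50,
    seed: int = 0,
    depth_mean: float = 10.0,
    depth_dispersion: float = 2.0,
    dirichlet_concentration: float = 100.0,
    n_anchors: int = 2,
) -> SimulationConfig:
    """Exchangeable-type config: per-gene base far-partner usage drawn U(0.2, 0.8)."""
    rng = np.random.default_rng(seed)
    genes = []
    for g in range(n_genes):
        anchors, name = _gene_layout(g, n_anchors, 2)
        usage = tuple(_two_partner_usage(float(rng.uniform(0.2, 0.8))) for _ in range(n_anchors))
        genes.append(GeneSpec(name=name, chrom="chr1", strand="+", anchors=anchors, usage={"*": usage}))
    return SimulationConfig(
        seed=seed,
        cell_types=default_cell_types(n_cells_per_type),
        genes=tuple(genes),
        dirichlet_concentration=dirichlet_concentration,
        depth_mean=depth_mean,
        depth_dispersion=depth_dispersion,
    )


def make_differential_config(
    n_planted: int = 5,
    n_null: int = 5,
    delta_usage: float = 0.4,
    n_cells_per_type: int = 200,
    seed: int = 0,
    depth_mean: float = 10.0,
    depth_dispersion: float = 2.0,
) -> SimulationConfig:
    """Two cell types in one tissue+compartment; planted genes shift far-partner
    usage by ``delta_usage`` between the types at a single-anchor gene."""
    cell_types = (
        CellTypeSpec("typeA", "lung", "immune", n_cells_per_type),
        CellTypeSpec("typeB", "lung", "immune", n_cells_per_type),
    )
    rng = np.random.default_rng(seed)
    genes = []
    for g in range(n_planted):
        anchors, name = _gene_layout(g, 1, 2)
        hi, lo = 0.5 + delta_usage / 2.0, 0.5 - delta_usage / 2.0
        genes.append(
            GeneSpec(
                name=name,
                chrom="chr1",
                strand="+",
                anchors=anchors,
                usage={"typeA": (_two_partner_usage(hi),), "typeB": (_two_partner_usage(lo),)},
            )
        )
    for g in range(n_planted, n_planted + n_null):
        anchors, name = _gene_layout(g, 1, 2)
        usage = (_two_partner_usage(float(rng.uniform(0.3, 0.7))),)
        genes.append(GeneSpec(name=name, chrom="chr1", strand="+", anchors=anchors, usage={"*": usage}))
    return SimulationConfig(
        seed=seed,
        cell_types=cell_types,
        genes=tuple(genes),
        depth_mean=depth_mean,
        depth_dispersion=depth_dispersion,
    )


def make_site_recovery_config(
    n_inert_anchors: int = 4,
    delta_usage: float = 0.6,
    n_cells_per_type: int = 100,
    seed: int = 0,
    depth_mean: float = 15.0,
) -> SimulationConfig:
    """One gene with one variable anchor hidden among inert anchors, two cell types."""
    cell_types = (
        CellTypeSpec("typeA", "lung", "immune", n_cells_per_type),
        CellTypeSpec("typeB", "lung", "immune", n_cells_per_type),
    )
    n_anchors = n_inert_anchors + 1
    anchors, name = _gene_layout(0, n_anchors, 2)
    variable_index = n_inert_anchors // 2
    hi, lo = 0.5 + delta_usage / 2.0, 0.5 - delta_usage / 2.0
    usage_a = tuple(
        _two_partner_usage(hi if i == variable_index else 0.5) for i in range(n_anchors)
    )
    usage_b = tuple(
        _two_partner_usage(lo if i == variable_index else 0.5) for i in range(n_anchors)
    )
    gene = GeneSpec(name=name, chrom="chr1", strand="+", anchors=anchors, usage={"typeA": usage_a, "typeB": usage_b})
    return SimulationConfig(seed=seed, cell_types=cell_types, genes=(gene,), depth_mean=depth_mean)


def make_subpopulation_config(
    n_cells: int = 240,
    usage_far_a: float = 0.9,
    usage_far_b: float = 0.1,
    proportion_a: float = 0.5,
    seed: int = 0,
    depth_mean: float = 12.0,
) -> SimulationConfig:
    """One cell type that is a hidden mixture of two usage states at a single anchor."""
    cell_types = (CellTypeSpec("typeA", "lung", "immune", n_cells),)
    anchors, name = _gene_layout(0, 1, 2)
    pooled = _two_partner_usage((usage_far_a + usage_far_b) / 2.0)
    gene = GeneSpec(name=name, chrom="chr1", strand="+", anchors=anchors, usage={"*": (pooled,)})
    sub = SubpopulationSpec(
        cell_type="typeA",
        gene=name,
        anchor_index=0,
        usage_a=_two_partner_usage(usage_far_a),
        usage_b=_two_partner_usage(usage_far_b),
        proportion_a=proportion_a,
    )
    return SimulationConfig(
        seed=seed, cell_types=cell_types, genes=(gene,), subpopulations=(sub,), depth_mean=depth_mean
    )


def make_trajectory_config(
    n_drift_genes: int = 1,
    n_null_genes: int = 0,
    n_cells: int = 500,
    start_far: float = 0.1,
    end_far: float = 0.9,
    seed: int = 0,
    depth_mean: float = 20.0,
) -> SimulationConfig:
    """Single cell type with pseudotime; drift genes blend usage start->end logistically."""
    cell_types = (CellTypeSpec("typeA", "testis", "other", n_cells),)
    genes, traj = [], []
    for g in range(n_drift_genes):
        anchors, name = _gene_layout(g, 1, 2)
        genes.append(
            GeneSpec(
                name=name,
                chrom="chr1",
                strand="+",
                anchors=anchors,
                usage={"*": (_two_partner_usage((start_far + end_far) / 2.0),)},
            )
        )
        traj.append(
            TrajectorySpec(
                gene=name,
                anchor_index=0,
                start=_two_partner_usage(start_far),
                end=_two_partner_usage(end_far),
            )
        )
    rng = np.random.default_rng(seed)
    for g in range(n_drift_genes, n_drift_genes + n_null_genes):
        anchors, name = _gene_layout(g, 1, 2)
        usage = (_two_partner_usage(float(rng.uniform(0.3, 0.7))),)
        genes.append(GeneSpec(name=name, chrom="chr1", strand="+", anchors=anchors, usage={"*": usage}))
    return SimulationConfig(
        seed=seed, cell_types=cell_types, genes=tuple(genes), trajectory=tuple(traj), depth_mean=depth_mean
    )
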