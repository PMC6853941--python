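"""Synthetic screens and toy interactomes with known ground truth.

The screen generator emulates a plate-based high-content experiment: DMSO
control wells, replicated single-drug wells plated at successive time
points, and once-measured combination wells whose phenotype realises a
planted decomposition c = alpha*a + beta*b + gamma*n_hat (n_hat drawn
uniformly from the orthogonal complement of the two single-effect
vectors).  Additive plate row/column artefacts, well-to-well noise and
per-cell noise around the well mean are layered on top, so every
preprocessing stage of the pipeline has something real to remove.

The interactome generator grows target modules of controllable
localization on a scale-free-like background graph, so localization and
separation statistics can be validated against planted structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import networkx as nx
import pandas as pd

from .normalize import META_COLUMNS, ROLE_COMBINATION, ROLE_CONTROL, ROLE_SINGLE

__all__ = [
    "ScreenSimConfig",
    "GroundTruth",
    "simulate_screen",
    "default_planted_pairs",
    "simulate_interactome",
]


@dataclass
class ScreenSimConfig:
    """Generative parameters of a synthetic screen.

    Magnitudes live on the normalised [0, 1] feature scale around a 0.5
    baseline.  The defaults mirror the screening protocol where one is
    stated -- six single-drug replicates plated at successive time points,
    combinations measured once, 384-well (16 x 24) plates -- and otherwise
    use values typical of a well-behaved morphological screen: strong
    drugs displace the phenotype by ~0.10 (at or above the D_P = 7
    strength cutoff at the default noise), weak drugs by ~0.03 (below
    it), well-to-well noise 0.004 s.d. per feature, cell-to-cell noise
    0.02 s.d., plate row/column artefacts 0.01 s.d.  The 48 control
    wells per plate stand in for the batch-wide DMSO pool that a
    many-plate screen accumulates.
    """

    n_drugs: int = 12
    n_strong: int = 3
    n_features: int = 10
    n_replicates: int = 6
    n_controls_per_plate: int = 48
    n_batches: int = 1
    plate_rows: int = 16
    plate_cols: int = 24
    baseline: float = 0.5
    strong_magnitude: float = 0.10
    weak_magnitude: float = 0.03
    well_noise_sd: float = 0.004
    cell_noise_sd: float = 0.02
    plate_effect_sd: float = 0.01
    cells_per_well: int = 100
    heavy_tailed_cells: bool = False
    pairs: list = field(default_factory=list)   # (i, j, alpha, beta, gamma)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_drugs, self.n_features, self.n_replicates,
               self.n_controls_per_plate, self.cells_per_well) <= 0:
            raise ValueError("all counts must be positive")
        if self.n_strong > self.n_drugs:
            raise ValueError("n_strong cannot exceed n_drugs")
        if self.n_features < 3 and any(p[4] > 0 for p in self.pairs):
            raise ValueError(
                "feature dimension < 3 cannot guarantee an orthogonal "
                "emergent direction"
            )

    @classmethod
    def from_json(cls, path: str) -> "ScreenSimConfig":
        with open(path) as fh:
            cfg = json.load(fh)
        cfg["pairs"] = [tuple(p) for p in cfg.get("pairs", [])]
        return cls(**cfg)


@dataclass
class GroundTruth:
    """Everything the generator planted, for recovery checks."""

    effects: dict               # drug -> true effect vector
    strong: dict                # drug -> bool
    pair_coefficients: dict     # (drug_a, drug_b) -> (alpha, beta, gamma)
    pair_classes: dict          # (drug_a, drug_b) -> (state_a, state_b, emergent)
    plate_row_effects: dict     # plate -> row-effect array
    plate_col_effects: dict     # plate -> col-effect array

    def to_json(self, path: str) -> None:
        payload = {
            "effects": {k: [float(x) for x in v] for k, v in self.effects.items()},
            "strong": {k: bool(v) for k, v in self.strong.items()},
            "pair_coefficients": {
                f"{a}|{b}": [float(x) for x in v]
                for (a, b), v in self.pair_coefficients.items()
            },
            "pair_classes": {
                f"{a}|{b}": [v[0], v[1], bool(v[2])]
                for (a, b), v in self.pair_classes.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _planted_class(alpha: float, beta: float, gamma: float) -> tuple[str, str, bool]:
    def state(v: float) -> str:
        if v < 1:
            return "decreased"
        if v > 1:
            return "increased"
        return "unchanged"

    return (state(alpha), state(beta), bool(gamma > 0))


def default_planted_pairs(
    n_drugs: int,
    n_pairs: int,
    rng: np.random.Generator,
    fraction_ni: float = 0.5,
    alpha_low: float = 0.3,
    alpha_high: float = 1.7,
    gamma_scale: float = 0.7,
    drugs: Sequence[int] | None = None,
) -> list[tuple]:
    """Sample a planted pair table mixing non-interactions with all classes.

    Interacting pairs draw each coefficient state independently
    (decreased/unchanged/increased for alpha and beta, emergent or not
    for gamma, re-drawn if all three come out neutral); ``gamma_scale``
    is expressed relative to the mean single-effect magnitude and
    converted to feature units by the screen generator.  ``drugs``
    restricts the sampled pairs to a subset of drug indices (e.g. the
    strong drugs, where modulation is detectable in the first place).
    """
    pool = list(drugs) if drugs is not None else list(range(n_drugs))
    all_pairs = [(pool[i], pool[j]) for i in range(len(pool))
                 for j in range(i + 1, len(pool))]
    if n_pairs > len(all_pairs):
        raise ValueError("more pairs requested than unordered drug pairs exist")
    idx = rng.choice(len(all_pairs), size=n_pairs, replace=False)
    chosen = [all_pairs[k] for k in idx]
    out = []
    for k, (i, j) in enumerate(chosen):
        if k < int(round(fraction_ni * len(chosen))):
            out.append((i, j, 1.0, 1.0, 0.0))
            continue
        while True:
            alpha = rng.choice([alpha_low, 1.0, alpha_high])
            beta = rng.choice([alpha_low, 1.0, alpha_high])
            gamma = rng.choice([0.0, gamma_scale])
            if (alpha, beta, gamma) != (1.0, 1.0, 0.0):
                break
        out.append((i, j, float(alpha), float(beta), float(gamma)))
    return out


def _orthogonal_unit(a: np.ndarray, b: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Uniform unit vector in the orthogonal complement of span(a, b)."""
    d = len(a)
    basis = np.linalg.qr(np.column_stack([a, b]))[0]
    for _ in range(100):
        v = rng.standard_normal(d)
        v -= basis @ (basis.T @ v)
        norm = np.linalg.norm(v)
        if norm > 1e-12:
            return v / norm
    raise RuntimeError("could not draw an orthogonal direction")


def simulate_screen(cfg: ScreenSimConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (cell table, plate map, ground truth) for a synthetic screen.

    Well means are baseline + plate row/column effect + treatment effect +
    well noise; cells scatter around the well mean with isotropic Gaussian
    noise (Student-t with 3 d.o.f. when ``heavy_tailed_cells``, to
    exercise the robustness of median aggregation).  Identical seeds give
    byte-identical outputs.
    """
    rng = np.random.default_rng(cfg.seed)
    d = cfg.n_features
    drugs = [f"D{i:03d}" for i in range(cfg.n_drugs)]
    strong = {drug: i < cfg.n_strong for i, drug in enumerate(drugs)}

    effects = {}
    for i, drug in enumerate(drugs):
        direction = rng.standard_normal(d)
        direction /= np.linalg.norm(direction)
        mag = cfg.strong_magnitude if strong[drug] else cfg.weak_magnitude
        effects[drug] = mag * direction

    pair_coeffs, pair_classes, combo_means = {}, {}, {}
    for i, j, alpha, beta, gamma in cfg.pairs:
        a_name, b_name = drugs[i], drugs[j]
        a_vec, b_vec = effects[a_name], effects[b_name]
        # planted gamma is relative to the pair's own effect scale
        pair_mag = 0.5 * (np.linalg.norm(a_vec) + np.linalg.norm(b_vec))
        gamma_units = gamma * pair_mag
        combo = alpha * a_vec + beta * b_vec
        if gamma_units > 0:
            combo = combo + gamma_units * _orthogonal_unit(a_vec, b_vec, rng)
        pair_coeffs[(a_name, b_name)] = (alpha, beta, gamma_units)
        pair_classes[(a_name, b_name)] = _planted_class(alpha, beta, gamma_units)
        combo_means[(a_name, b_name)] = combo

    # enumerate treatments: per batch, singles x replicates; combinations once
    treatments = []       # (role, drug_a, drug_b, replicate, time_order, batch)
    for batch in range(cfg.n_batches):
        for drug in drugs:
            for rep in range(1, cfg.n_replicates + 1):
                treatments.append((ROLE_SINGLE, drug, "", rep, rep, batch))
    for k, (a_name, b_name) in enumerate(combo_means):
        batch = k % cfg.n_batches
        treatments.append((ROLE_COMBINATION, a_name, b_name, 1, 1, batch))

    capacity = cfg.plate_rows * cfg.plate_cols - cfg.n_controls_per_plate
    if capacity <= 0:
        raise ValueError("plate has no room for treatments beside controls")

    meta_rows, cell_frames = [], []
    plate_row_effects, plate_col_effects = {}, {}
    cursor = 0
    plate_id = 0
    by_batch: dict[int, list] = {}
    for t in treatments:
        by_batch.setdefault(t[5], []).append(t)

    for batch in sorted(by_batch):
        batch_treatments = by_batch[batch]
        # randomized plate layout: singles and combinations interleave, so
        # no plate is dominated by strongly perturbed wells
        order = rng.permutation(len(batch_treatments))
        batch_treatments = [batch_treatments[i] for i in order]
        for start in range(0, len(batch_treatments), capacity):
            chunk = batch_treatments[start:start + capacity]
            plate = f"P{plate_id:03d}"
            plate_id += 1
            row_eff = rng.normal(0.0, cfg.plate_effect_sd, size=cfg.plate_rows)
            col_eff = rng.normal(0.0, cfg.plate_effect_sd, size=cfg.plate_cols)
            plate_row_effects[plate] = row_eff
            plate_col_effects[plate] = col_eff

            # controls first, then the treatment chunk
            entries = [(ROLE_CONTROL, "", "", r + 1, r + 1, batch)
                       for r in range(cfg.n_controls_per_plate)] + chunk
            # fill a compact block of rows (as a real screen would) so the
            # median polish sees full rows; wells are shuffled within it
            n_rows_used = int(np.ceil(len(entries) / cfg.plate_cols))
            block = rng.permutation(n_rows_used * cfg.plate_cols)[: len(entries)]
            positions = block
            for (role, a_name, b_name, rep, order, _), pos in zip(entries, positions):
                r, c = divmod(int(pos), cfg.plate_cols)
                well = f"{chr(ord('A') + r)}{c + 1:02d}"
                mean = np.full(d, cfg.baseline) + row_eff[r] + col_eff[c]
                if role == ROLE_SINGLE:
                    mean = mean + effects[a_name]
                elif role == ROLE_COMBINATION:
                    mean = mean + combo_means[(a_name, b_name)]
                mean = mean + rng.normal(0.0, cfg.well_noise_sd, size=d)

                n_cells = cfg.cells_per_well
                if cfg.heavy_tailed_cells:
                    noise = cfg.cell_noise_sd * rng.standard_t(3, size=(n_cells, d))
                else:
                    noise = rng.normal(0.0, cfg.cell_noise_sd, size=(n_cells, d))
                cells = mean[None, :] + noise
                frame = pd.DataFrame(cells, columns=[f"f{k:03d}" for k in range(d)])
                frame.insert(0, "cell", np.arange(n_cells))
                frame.insert(0, "well", well)
                frame.insert(0, "plate", plate)
                cell_frames.append(frame)
                meta_rows.append(
                    {
                        "plate": plate, "well": well, "row": r, "col": c,
                        "batch": batch, "role": role,
                        "drug_a": a_name, "drug_b": b_name,
                        "replicate": rep, "time_order": order,
                        "cell_count": n_cells,
                    }
                )

    cells = pd.concat(cell_frames, ignore_index=True)
    meta = pd.DataFrame(meta_rows).set_index(["plate", "well"])
    truth = GroundTruth(
        effects=effects,
        strong=strong,
        pair_coefficients=pair_coeffs,
        pair_classes=pair_classes,
        plate_row_effects=plate_row_effects,
        plate_col_effects=plate_col_effects,
    )
    return cells, meta, truth


# ---------------------------------------------------------------------------
# toy interactomes
# ---------------------------------------------------------------------------

def simulate_interactome(
    n_nodes: int = 500,
    attachment: int = 3,
    modules: Sequence[dict] | None = None,
    seed: int | None = None,
) -> tuple[nx.Graph, dict]:
    """Scale-free-like background graph with planted target modules.

    Each module spec is a dict with ``size``, ``locality`` (lambda in
    [0, 1]: probability of growing the module through a neighbor of the
    current members rather than a uniformly random node; 1 gives a
    connected module, 0 a uniform random set) and optionally
    ``overlap_with`` = (module index, fraction) to share that fraction of
    proteins with an earlier module.  Returns the graph and a mapping
    module name -> protein set.
    """
    rng = np.random.default_rng(seed)
    graph = nx.barabasi_albert_graph(n_nodes, attachment,
                                     seed=int(rng.integers(2**31 - 1)))
    modules = modules or []
    target_sets: dict = {}
    names = []
    for m_index, spec in enumerate(modules):
        size = int(spec["size"])
        lam = float(spec.get("locality", 1.0))
        if size >= n_nodes:
            raise ValueError("module size must be below the node count")
        members: set = set()
        if "overlap_with" in spec and spec["overlap_with"] is not None:
            other_index, fraction = spec["overlap_with"]
            other = sorted(target_sets[names[other_index]])
            n_shared = int(round(fraction * size))
            if n_shared > len(other):
                raise ValueError("requested overlap exceeds the other module")
            members |= set(rng.choice(other, size=n_shared, replace=False))
        if not members:
            members.add(int(rng.integers(n_nodes)))
        while len(members) < size:
            grow_local = rng.random() < lam
            if grow_local:
                frontier = sorted(
                    set().union(*(graph.neighbors(v) for v in members)) - members
                )
                if frontier:
                    members.add(int(rng.choice(frontier)))
                    continue
            outside = sorted(set(range(n_nodes)) - members)
            members.add(int(rng.choice(outside)))
        name = f"M{m_index}"
        names.append(name)
        target_sets[name] = set(members)
    return graph, target_sets
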