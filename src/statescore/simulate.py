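"""Synthetic labeled single-cell data and perturbagen reference databases.

The generator emulates the statistical structure the state model actually
consumes: per-gene Bernoulli *detection* in each cell.  Every gene has a
baseline detection probability p0 (uniform on [0.01, 0.5] by default); a
planted up-signature is detected more often in state1 cells (p1 = p0 +
delta) and a down-signature less often (p1 = p0 - delta), both clamped to
[0.002, 0.95]; all other genes are uninformative (p1 = p0).  Count mode
multiplies each detection by a positive geometric count (mean 3), so
binarizing the counts reproduces the binary-mode field exactly under the
same seed.  This is deliberately not a full scRNA-seq count simulator: no
doublets, batch effects or ambient RNA — presence/absence is the sufficient
structure for everything downstream.

``simulate_reference`` builds a desk-scale perturbagen database with i.i.d.
standard-normal background signatures plus one planted *mimicker* (scores
shifted +3 on the up-signature, -3 on the down) and one *reverser* (the
mirror image), giving ground truth for connectivity search tests.

All randomness flows from a single seed through named ``SeedSequence``
children, so outputs are bit-identical across runs and independent of which
optional outputs are requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    BinaryMatrix,
    ExpressionMatrix,
    GeneUniverse,
    LabeledDataset,
)
from .connectivity import ReferenceSignatureDB
from .errors import ValidationError

__all__ = [
    "SyntheticSpec",
    "SyntheticTruth",
    "SimulationResult",
    "simulate_labeled",
    "simulate_reference",
]

_P_CLIP = (0.002, 0.95)


@dataclass
class SyntheticSpec:
    """Study conditions for the labeled-data generator.

    Defaults define the reference setting used throughout the test battery:
    2000 genes, 50-gene up and down signatures, detection shift delta=0.3,
    500 cells per state.
    """

    n_genes: int = 2000
    n_up: int = 50
    n_down: int = 50
    n_cells_per_state: tuple[int, int] = (500, 500)
    delta: float = 0.3
    baseline_range: tuple[float, float] = (0.01, 0.5)
    count_mean: float = 3.0
    emit: str = "binary"
    seed: int = 0
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValidationError("delta must be >= 0")
        if self.n_up + self.n_down > self.n_genes:
            raise ValidationError("signature sizes exceed the number of genes")
        if min(self.n_cells_per_state) < 1 or self.n_genes < 1:
            raise ValidationError("need at least one cell per state and one gene")
        if self.emit not in ("binary", "counts"):
            raise ValidationError("emit must be 'binary' or 'counts'")
        if self.replicate < 0:
            raise ValidationError("replicate must be >= 0")


@dataclass
class SyntheticTruth:
    """Planted ground truth: signature gene lists and per-gene (p0, p1)."""

    s_up: list[str]
    s_down: list[str]
    p0: np.ndarray
    p1: np.ndarray
    universe: GeneUniverse = field(repr=False, default=None)


@dataclass
class SimulationResult:
    """Output of :func:`simulate_labeled`.

    ``dataset`` (binary matrix + labels) is always present; ``counts`` is
    filled only in counts mode and binarizes back to ``dataset.matrix``.
    """

    dataset: LabeledDataset
    truth: SyntheticTruth
    counts: ExpressionMatrix | None = None

    @property
    def labels(self) -> np.ndarray:
        return self.dataset.labels


def _children(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_labeled(spec: SyntheticSpec) -> SimulationResult:
    """Draw a labeled dataset with planted up/down detection signatures.

    The planted truth (which genes form the signatures, their detection
    probabilities) depends only on ``spec.seed``; ``spec.replicate`` selects
    an independent draw of cells from that same truth, which is how held-out
    validation sets are produced.
    """
    children = _children(spec.seed, 3 + 2 * spec.replicate)
    rng_p = children[0]
    rng_detect, rng_counts = children[1 + 2 * spec.replicate :]
    G = spec.n_genes
    symbols = tuple(f"G{i:05d}" for i in range(G))
    universe = GeneUniverse(symbols)

    p0 = rng_p.uniform(*spec.baseline_range, size=G)
    perm = rng_p.permutation(G)
    up_idx = perm[: spec.n_up]
    down_idx = perm[spec.n_up : spec.n_up + spec.n_down]
    p1 = p0.copy()
    p1[up_idx] = p0[up_idx] + spec.delta
    p1[down_idx] = p0[down_idx] - spec.delta
    p0 = np.clip(p0, *_P_CLIP)
    p1 = np.clip(p1, *_P_CLIP)

    n0, n1 = spec.n_cells_per_state
    labels = np.concatenate([np.zeros(n0, int), np.ones(n1, int)])
    probs = np.vstack([np.tile(p0, (n0, 1)), np.tile(p1, (n1, 1))])
    detected = (rng_detect.random(probs.shape) < probs).astype(np.uint8)

    cell_ids = [f"cell{i:05d}_s{labels[i]}" for i in range(n0 + n1)]
    bm = BinaryMatrix(cell_ids=cell_ids, universe=universe, g=detected)
    dataset = LabeledDataset(matrix=bm, labels=labels)
    truth = SyntheticTruth(
        s_up=[symbols[i] for i in sorted(up_idx)],
        s_down=[symbols[i] for i in sorted(down_idx)],
        p0=p0,
        p1=p1,
        universe=universe,
    )

    counts = None
    if spec.emit == "counts":
        # positive count given detection: geometric (support >= 1), mean 3
        p_geom = 1.0 / spec.count_mean
        mag = rng_counts.geometric(p_geom, size=detected.shape)
        counts = ExpressionMatrix(
            cell_ids=cell_ids,
            gene_ids=list(symbols),
            counts=(detected * mag).astype(np.int64),
        )
    return SimulationResult(dataset=dataset, truth=truth, counts=counts)


def simulate_reference(
    n_signatures: int,
    ref_universe: GeneUniverse,
    query_truth: SyntheticTruth,
    seed: int = 0,
    planted_shift: float = 3.0,
    min_signature_coverage: float = 0.5,
) -> tuple[ReferenceSignatureDB, pd.DataFrame]:
    """Background signatures plus one planted mimicker and one reverser.

    Background perturbagens get i.i.d. N(0,1) per-gene scores.  The
    mimicker's scores are shifted by ``+planted_shift`` on the planted
    up-signature genes and ``-planted_shift`` on the down genes — it
    *induces* the state0 -> state1 transition; the reverser is the mirror
    image.  Returns the database and a roles table (signature, perturbagen,
    cell_type, role).
    """
    if n_signatures < 0:
        raise ValidationError("n_signatures must be >= 0")
    ref = set(ref_universe.symbols)
    sig_genes = set(query_truth.s_up) | set(query_truth.s_down)
    covered = len(sig_genes & ref) / max(len(sig_genes), 1)
    if covered < min_signature_coverage:
        raise ValidationError(
            f"reference universe covers only {covered:.0%} of the planted "
            "signature genes"
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    G = len(ref_universe)
    names, roles, cols = [], [], []

    up_mask = np.fromiter((g in set(query_truth.s_up) for g in ref_universe), bool, G)
    down_mask = np.fromiter(
        (g in set(query_truth.s_down) for g in ref_universe), bool, G
    )

    for i in range(n_signatures):
        names.append(f"sig{i:04d}")
        roles.append("background")
        cols.append(rng.standard_normal(G))

    mim = rng.standard_normal(G)
    mim[up_mask] += planted_shift
    mim[down_mask] -= planted_shift
    names.append("sig_mimicker")
    roles.append("mimicker")
    cols.append(mim)

    rev = rng.standard_normal(G)
    rev[up_mask] -= planted_shift
    rev[down_mask] += planted_shift
    names.append("sig_reverser")
    roles.append("reverser")
    cols.append(rev)

    scores = pd.DataFrame(
        np.column_stack(cols), index=list(ref_universe.symbols), columns=names
    )
    meta = pd.DataFrame(
        {
            "perturbagen": [n.replace("sig", "drug") for n in names],
            "cell_type": "CT1",
        },
        index=names,
    )
    db = ReferenceSignatureDB(
        ref_universe=ref_universe, scores=scores, meta=meta, source="synthetic"
    )
    roles_df = meta.assign(role=roles)
    return db, roles_df
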