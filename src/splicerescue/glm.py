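"""Parameter-response linear model for junction counts.

The number of junctions a run reports responds to the three spatial
parameters of the pipeline — minimum split size (MS), maximum candidate
distance (MD) and boundary buffer (BB).  Fitting

    count = β0 + β1·MS + β2·MD + β3·BB

by ordinary least squares over a grid of runs yields a predictor of the
junction count at any parameter combination (the identity-link "general
linear model"; no interactions, no count link).  β1 is expected to be
non-positive: raising MS strictly shrinks the admissible split set.

Grid orchestration reuses the expensive alignment work: the first pass does
not depend on (MS, MD, BB) at all, and the half alignments produced by
splitting at the smallest MS of the grid serve every larger MS — a half
alignment belongs to grid point MS = m iff both of its halves are at least m
long.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .align import Alignment, AlignerConfig, Read, first_pass, second_pass
from .compare import subtract_junctions
from .splitcore import (
    Params,
    cluster_junctions,
    filter_junctions,
    half_queries,
    parse_half_id,
    split_read,
)

_PREDICTORS = ("MS", "MD", "BB")


@dataclass(frozen=True)
class GridRun:
    ms: int
    md: int
    bb: int
    junction_count: int


@dataclass(frozen=True)
class GlmFit:
    """OLS fit of junction count on (MS, MD, BB)."""

    beta: tuple[float, float, float, float]  # intercept, MS, MD, BB
    bse: tuple[float, float, float, float]  # standard errors, same order
    r_squared: float
    residuals: tuple[float, ...]

    @property
    def intercept(self) -> float:
        return self.beta[0]


def _junctions_at(
    half_alignments: Sequence[Alignment],
    read_lengths: Mapping[str, int],
    params: Params,
) -> list:
    """Junctions from a pre-computed half-alignment pool at given params."""
    from .splitcore import find_matched_pairs

    admissible = []
    for aln in half_alignments:
        read_id, offset, _side = parse_half_id(aln.query_id)
        L = read_lengths[read_id]
        if offset >= params.min_split_size and L - offset >= params.min_split_size:
            admissible.append(aln)
    pairs = find_matched_pairs(admissible, params)
    junctions = cluster_junctions(pairs, params.boundary_buffer)
    return filter_junctions(junctions, params.min_support)


def run_parameter_grid(
    samples: Mapping[str, Sequence[Read]],
    expanded_genome: Mapping[str, str],
    genome: Mapping[str, str],
    base_params: Params,
    grid: Iterable[tuple[int, int, int]],
    aligner: AlignerConfig | None = None,
) -> list[GridRun]:
    """One junction count per (MS, MD, BB) grid point.

    ``samples`` holds one read pool (plain junction count) or two, in which
    case the count is the case-minus-control unique set of the first sample
    against the second, matching how the model was conceived.  Repeated grid
    points are deduplicated with a warning.  Deterministic for fixed inputs.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty parameter grid")
    seen: dict[tuple[int, int, int], None] = {}
    for point in grid:
        if point in seen:
            warnings.warn(f"duplicate grid point {point} ignored", stacklevel=2)
        seen[point] = None
    points = list(seen)
    if len(samples) not in (1, 2):
        raise ValueError("grid runs take one or two samples")
    cfg = aligner or AlignerConfig(max_good_alignments=base_params.max_good_alignments)
    min_ms = min(p[0] for p in points)

    pools: list[tuple[list[Alignment], dict[str, int]]] = []
    for reads in samples.values():
        _, unmapped = first_pass(reads, expanded_genome, cfg)
        halves = []
        for read in unmapped:
            halves.extend(half_queries(split_read(read, min_ms)))
        pools.append((second_pass(halves, genome, cfg), {r.id: len(r.seq) for r in unmapped}))

    runs = []
    for ms, md, bb in points:
        params = replace(
            base_params, min_split_size=ms, max_distance=md, boundary_buffer=bb
        )
        per_sample = [_junctions_at(alns, lengths, params) for alns, lengths in pools]
        if len(per_sample) == 2:
            count = len(subtract_junctions(per_sample[0], per_sample[1], bb))
        else:
            count = len(per_sample[0])
        runs.append(GridRun(ms, md, bb, count))
    return runs


def runs_to_frame(runs: Sequence[GridRun]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "MS": [r.ms for r in runs],
            "MD": [r.md for r in runs],
            "BB": [r.bb for r in runs],
            "count": [r.junction_count for r in runs],
        }
    )


def fit_glm(runs: Sequence[GridRun]) -> GlmFit:
    """Ordinary least squares of count on MS, MD, BB with intercept.

    Requires at least four runs and a full-rank design; a rank-deficient
    design raises an error naming the collinear (constant) predictors.
    """
    if len(runs) < 4:
        raise ValueError(f"need >= 4 grid runs to fit 4 coefficients, got {len(runs)}")
    frame = runs_to_frame(runs)
    X = frame[list(_PREDICTORS)].to_numpy(dtype=float)
    y = frame["count"].to_numpy(dtype=float)
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        constant = [
            name for name, col in zip(_PREDICTORS, X.T) if np.ptp(col) == 0
        ]
        raise ValueError(
            "rank-deficient design; collinear predictors: "
            + (", ".join(constant) if constant else "linearly dependent columns")
        )
    result = sm.OLS(y, design).fit()
    with np.errstate(divide="ignore", invalid="ignore"):
        r_squared = float(result.rsquared)
    if not np.isfinite(r_squared):  # constant response: zero total variance
        r_squared = 1.0 if np.allclose(result.resid, 0.0) else 0.0
    return GlmFit(
        beta=tuple(result.params),
        bse=tuple(result.bse),
        r_squared=r_squared,
        residuals=tuple(result.resid),
    )


def predict_count(fit: GlmFit, ms: float, md: float, bb: float) -> float:
    """β0 + β1·MS + β2·MD + β3·BB, clipped below at 0 for reporting."""
    b0, b1, b2, b3 = fit.beta
    return max(0.0, b0 + b1 * ms + b2 * md + b3 * bb)


def write_fit_summary(fit: GlmFit, runs: Sequence[GridRun], path) -> None:
    """Tab-separated grid table plus coefficient block."""
    with open(path, "w") as out:
        out.write("MS\tMD\tBB\tcount\n")
        for r in runs:
            out.write(f"{r.ms}\t{r.md}\t{r.bb}\t{r.junction_count}\n")
        out.write("#coef\tintercept\tMS\tMD\tBB\n")
        out.write("#beta\t" + "\t".join(f"{b:.6g}" for b in fit.beta) + "\n")
        out.write("#se\t" + "\t".join(f"{s:.6g}" for s in fit.bse) + "\n")
        out.write(f"#r_squared\t{fit.r_squared:.6g}\n")
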