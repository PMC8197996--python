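"""Expression matrices, aging-stage handling and cubic-spline preprocessing.

Cross-sectional samples ordered by donor age are treated as a pseudo-time
series: the dynamic models downstream equate age order with system time.
Each stage's sparse age grid is densified by per-node cubic-spline
interpolation (default 500 evenly spaced pseudo-time points), which is the
sample-size inflation used to avoid over-fitting in the per-node
least-squares fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

STAGES = ("young_adult", "middle_aged", "elderly")


@dataclass(frozen=True)
class StageDefinition:
    """Inclusive age window for one aging stage (windows may overlap)."""

    stage: str
    age_min: float
    age_max: float


#: default skin-aging stage windows (years); deliberately overlapping
DEFAULT_STAGES = (
    StageDefinition("young_adult", 19, 45),
    StageDefinition("middle_aged", 43, 65),
    StageDefinition("elderly", 64, 86),
)


@dataclass
class ExpressionDataset:
    """node_id x sample expression matrix for one stage.

    ``values`` is a DataFrame indexed by node_id with float age (or
    pseudo-time) column labels, ordered ascending.
    """

    stage: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        ages = np.asarray(self.values.columns, dtype=float)
        if np.any(np.diff(ages) < 0):
            raise ValueError("sample columns must be ordered by age ascending")

    @property
    def sample_ages(self) -> np.ndarray:
        return np.asarray(self.values.columns, dtype=float)

    @property
    def node_ids(self) -> list[str]:
        return list(self.values.index)

    def trajectory(self, node_id: str) -> np.ndarray:
        return self.values.loc[node_id].to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


def split_stages(values: pd.DataFrame, ages: np.ndarray,
                 defs: tuple[StageDefinition, ...] = DEFAULT_STAGES,
                 min_samples: int = 4) -> dict[str, ExpressionDataset]:
    """Partition age-ordered samples into (possibly overlapping) stages.

    A sample belongs to every stage whose inclusive [age_min, age_max]
    window contains its age.  Stages with fewer than ``min_samples``
    samples are rejected because the cubic spline downstream needs at
    least four knots.
    """
    ages = np.asarray(ages, dtype=float)
    if ages.shape[0] != values.shape[1]:
        raise ValueError("ages must align with expression columns")
    order = np.argsort(ages, kind="stable")
    out: dict[str, ExpressionDataset] = {}
    for d in defs:
        cols = [i for i in order if d.age_min <= ages[i] <= d.age_max]
        if len(cols) < min_samples:
            raise ValueError(
                f"stage {d.stage!r} has {len(cols)} samples; "
                f"at least {min_samples} needed for spline interpolation"
            )
        sub = values.iloc[:, cols].copy()
        sub.columns = ages[cols]
        out[d.stage] = ExpressionDataset(d.stage, sub)
    return out


def _average_duplicate_ages(ds: ExpressionDataset) -> tuple[np.ndarray, np.ndarray]:
    """Collapse repeated ages by averaging their expression columns."""
    ages = ds.sample_ages
    mat = ds.values.to_numpy(dtype=float)
    uniq, inv = np.unique(ages, return_inverse=True)
    if uniq.size == ages.size:
        return uniq, mat
    avg = np.zeros((mat.shape[0], uniq.size))
    counts = np.bincount(inv)
    np.add.at(avg.T, inv, mat.T)
    return uniq, avg / counts


def spline_interpolate(ds: ExpressionDataset, n_out: int = 500,
                       bc_type: str = "not-a-knot") -> ExpressionDataset:
    """Per-node cubic-spline interpolation onto ``n_out`` evenly spaced
    pseudo-time points spanning the stage's age range.

    Duplicate ages are averaged before fitting the spline.  The
    interpolant passes through the (averaged) original samples exactly
    and reproduces polynomial trajectories up to degree three.
    """
    ages, mat = _average_duplicate_ages(ds)
    if ages.size < 4:
        raise ValueError("cubic spline interpolation needs >= 4 distinct ages")
    if not np.all(np.isfinite(mat)):
        raise ValueError("expression matrix contains non-finite values")
    spline = CubicSpline(ages, mat, axis=1, bc_type=bc_type)
    grid = np.linspace(ages[0], ages[-1], n_out)
    out = pd.DataFrame(spline(grid), index=ds.values.index, columns=grid)
    return ExpressionDataset(ds.stage, out)


def read_expression(path, stage: str = "young_adult") -> ExpressionDataset:
    """Read a TSV expression matrix (rows node_id, columns ages)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.columns = df.columns.astype(float)
    return ExpressionDataset(stage, df)


def write_expression(ds: ExpressionDataset, path) -> None:
    ds.values.to_csv(path, sep="\t", index_label="node_id")
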