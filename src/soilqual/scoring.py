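"""Composite soil indices: SQI (radar-area method) and enzyme EMF.

Two aggregation schemes are implemented:

* **SQI** — each soil property is first rescaled to a directional linear
  score ``Li`` in (0, 1] by min-max normalization over the analyzed plot
  set: ``Li = v / v_max`` where higher values mean better soil
  ("more is better": nutrients, SOC) and ``Li = v_min / v`` where lower
  values do ("less is better": salt).  The per-plot index is the area of
  the regular radar polygon spanned by the scores,

      SQI = 0.5 * sin(2*pi/n) * sum_i Li^2,

  with ``n`` scored properties.  A conventional alternative that uses
  adjacent-product sector areas (``sum_i Li * L_{i+1}``) is available as
  ``variant="adjacent"`` for sensitivity analysis.

* **EMF** — ecosystem multifunctionality: each enzyme activity column is
  Z-standardized over the analyzed plots (sample sd, N-1 denominator)
  and the per-plot EMF is the row mean of the Z-scores.

Both scoring sets (the min/max, mean and sd references) are pooled over
*all* plots supplied, not per treatment, so treatment contrasts of the
indices are well defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trial import Direction, PlotRecord, records_to_frame

__all__ = [
    "DEFAULT_SQI_PROPERTIES",
    "DEFAULT_EMF_ENZYMES",
    "linear_scores",
    "sqi",
    "sqi_upper_bound",
    "emf",
    "score_dataset",
    "ScoreTable",
]

#: Default six-property SQI set: salt scored "less is better", the rest
#: "more is better".
DEFAULT_SQI_PROPERTIES: dict[str, Direction] = {
    "salt": Direction.LESS_IS_BETTER,
    "TN": Direction.MORE_IS_BETTER,
    "avN": Direction.MORE_IS_BETTER,
    "avP": Direction.MORE_IS_BETTER,
    "avK": Direction.MORE_IS_BETTER,
    "SOC": Direction.MORE_IS_BETTER,
}

#: Default enzyme panel for EMF: C-cycle (BG, CE) and N-cycle (NAG, LAP)
#: extracellular enzymes.
DEFAULT_EMF_ENZYMES: tuple[str, ...] = ("BG", "CE", "NAG", "LAP")


def linear_scores(values, direction: Direction) -> np.ndarray:
    """Directional min-max linear scores ``Li`` for one property.

    The favourable extreme (max for "more is better", min for "less is
    better") is taken over the supplied values, so a constant column
    scores 1 everywhere.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot score an empty value set")
    if direction is Direction.MORE_IS_BETTER:
        return v / v.max()
    if direction is Direction.LESS_IS_BETTER:
        if np.any(v <= 0):
            raise ValueError("'less is better' scoring requires strictly positive values")
        return v.min() / v
    raise ValueError(f"direction {direction} is not scoreable")


def sqi(scores, variant: str = "printed") -> np.ndarray:
    """Radar-polygon area index from per-plot linear scores.

    Parameters
    ----------
    scores
        Array of shape (plots, n) with every entry in (0, 1].
    variant
        ``"printed"`` uses ``0.5 * sin(2*pi/n) * sum Li^2``;
        ``"adjacent"`` uses the adjacent-product polygon area
        ``0.5 * sin(2*pi/n) * sum Li * L_{i+1}`` (cyclic).
    """
    L = np.atleast_2d(np.asarray(scores, dtype=float))
    n = L.shape[1]
    if n < 3:
        raise ValueError(f"radar area needs at least 3 properties, got {n}")
    if np.any(L <= 0) or np.any(L > 1):
        raise ValueError("linear scores must lie in (0, 1]")
    factor = 0.5 * np.sin(2.0 * np.pi / n)
    if variant == "printed":
        return factor * np.sum(L**2, axis=1)
    if variant == "adjacent":
        return factor * np.sum(L * np.roll(L, -1, axis=1), axis=1)
    raise ValueError(f"unknown SQI variant {variant!r}")


def sqi_upper_bound(n: int) -> float:
    """Maximum attainable SQI (all scores 1) for ``n`` properties."""
    return 0.5 * n * np.sin(2.0 * np.pi / n)


def emf(enzyme_matrix) -> tuple[np.ndarray, np.ndarray]:
    """Z-score ecosystem multifunctionality.

    Returns ``(z, emf)``: the plots x enzymes Z-score matrix (sample sd)
    and the per-plot row mean.  Raises on a zero-variance column since
    its Z-scores are undefined.
    """
    if isinstance(enzyme_matrix, pd.DataFrame):
        names = list(enzyme_matrix.columns)
        x = enzyme_matrix.to_numpy(dtype=float)
    else:
        x = np.atleast_2d(np.asarray(enzyme_matrix, dtype=float))
        names = [f"enzyme{j}" for j in range(x.shape[1])]
    if x.shape[0] < 2:
        raise ValueError("EMF needs at least 2 plots")
    sd = x.std(axis=0, ddof=1)
    for j, s in enumerate(sd):
        if s == 0:
            raise ValueError(f"enzyme {names[j]!r} has zero variance; Z-score undefined")
    z = (x - x.mean(axis=0)) / sd
    return z, z.mean(axis=1)


@dataclass
class ScoreTable:
    """Per-plot scores of one dataset.

    Attributes
    ----------
    frame
        One row per plot: treatment, replicate, ``Li_<property>`` columns,
        ``SQI``, ``Z_<enzyme>`` columns and ``EMF``.
    n_properties
        Number of properties entering the SQI.
    variant
        Radar-area variant used for SQI.
    """

    frame: pd.DataFrame
    n_properties: int
    variant: str

    @property
    def sqi(self) -> pd.Series:
        return self.frame["SQI"]

    @property
    def emf(self) -> pd.Series:
        return self.frame["EMF"]

    @property
    def upper_bound(self) -> float:
        return sqi_upper_bound(self.n_properties)


def score_dataset(
    records: list[PlotRecord] | pd.DataFrame,
    sqi_properties: dict[str, Direction] | None = None,
    emf_enzymes: tuple[str, ...] | list[str] | None = None,
    variant: str = "printed",
) -> ScoreTable:
    """Score every plot of a trial: directional Li scores, SQI and EMF.

    The scoring references (per-property min/max, per-enzyme mean/sd)
    are pooled over all supplied plots.
    """
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    props = dict(sqi_properties) if sqi_properties is not None else dict(DEFAULT_SQI_PROPERTIES)
    enzymes = list(emf_enzymes) if emf_enzymes is not None else list(DEFAULT_EMF_ENZYMES)
    for name in list(props) + enzymes:
        if name not in frame.columns:
            raise ValueError(f"variable {name!r} is missing from the plot data")
    if len(props) < 3:
        raise ValueError("SQI needs at least 3 scored properties")

    out = frame[["treatment", "replicate"]].copy()
    li = np.column_stack(
        [linear_scores(frame[name].to_numpy(float), d) for name, d in props.items()]
    )
    for j, name in enumerate(props):
        out[f"Li_{name}"] = li[:, j]
    out["SQI"] = sqi(li, variant=variant)

    z, e = emf(frame[enzymes])
    for j, name in enumerate(enzymes):
        out[f"Z_{name}"] = z[:, j]
    out["EMF"] = e
    return ScoreTable(frame=out, n_properties=len(props), variant=variant)
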