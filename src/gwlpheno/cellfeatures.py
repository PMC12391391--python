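"""Per-cell intensity normalisation and cell-cycle/p21/multinucleation gating.

Raw integrated DNA, mean EdU and mean p21 intensities come in arbitrary
units that differ between experiments. Each distribution is normalised by
the location of the *first peak* of the corresponding distribution in an
untreated reference population of the same line, so the DNA first peak maps
to 1 genome equivalent (the 2N mode of that line — for aneuploid lines
"2N" means the first peak, a relative-ploidy convention). Cell areas are
divided by the reference median area.

Gating on the normalised table assigns every cell to exactly one of
{2N, S, 4N, 8N+}: EdU-positive cells are S regardless of DNA content, the
rest are split by DNA thresholds. p21 positivity and multinucleation are
independent boolean flags.

Column convention: raw tables carry ``dna``, ``edu``, ``p21``, ``area``,
``nuclei``; normalisation appends ``dna_norm``, ``edu_norm``, ``p21_norm``,
``area_norm``. The presence of the ``*_norm`` columns is the raw/normalised
flag and survives CSV round-trips.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

log = logging.getLogger(__name__)

RAW_COLUMNS = ("condition", "dose_um", "dna", "edu", "p21", "area", "nuclei")
NORM_COLUMNS = ("dna_norm", "edu_norm", "p21_norm", "area_norm")

#: minimum relative KDE height for a mode to count as a peak
_PEAK_HEIGHT_FLOOR = 0.10


@dataclass(frozen=True)
class GateConfig:
    """Classification thresholds on the normalised scale.

    DNA gates default to the midpoints between the 2N/4N and 4N/8N peak
    locations (1, 2 and 4 genome equivalents) on the linear scale. EdU+ and
    p21+ default to 3x the normalised first peak, i.e. 3x the mode of the
    negative population.
    """

    t_2n4n: float = 1.5
    t_4n8n: float = 3.0
    edu_pos: float = 3.0
    p21_pos: float = 3.0
    min_nuclei_multi: int = 2

    def __post_init__(self) -> None:
        if not (1.0 < self.t_2n4n < self.t_4n8n):
            raise ValueError("DNA gates must satisfy 1 < t_2N4N < t_4N8N")


@dataclass
class PopulationSummary:
    """Class proportions (%, summing to 100) and derived population metrics."""

    pct_2n: float
    pct_s: float
    pct_4n: float
    pct_8n: float
    pct_p21_pos: float
    pct_multinucleated: float
    median_area_norm: float
    n_cells: int

    @property
    def proportions(self) -> np.ndarray:
        """Ordered (2N, S, 4N, 8N+) percentages."""
        return np.array([self.pct_2n, self.pct_s, self.pct_4n, self.pct_8n])

    def as_dict(self) -> dict:
        return asdict(self)


def find_first_peak(values, bandwidth_rule: str = "silverman",
                    grid_size: int = 1024) -> float:
    """Location of the lowest local maximum of a KDE of ``values``.

    Local maxima below ``10%`` of the global KDE maximum are ignored as
    noise bumps. A constant sample returns that constant.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    if values.size < 50:
        log.warning("first-peak estimate from only %d values", values.size)
    if np.ptp(values) == 0:
        return float(values[0])

    kde = gaussian_kde(values, bw_method=bandwidth_rule)
    h = kde.factor * values.std(ddof=1)
    grid = np.linspace(values.min() - 3 * h, values.max() + 3 * h, grid_size)
    dens = kde(grid)

    interior = (dens[1:-1] >= dens[:-2]) & (dens[1:-1] >= dens[2:])
    peaks = np.flatnonzero(interior) + 1
    peaks = peaks[dens[peaks] >= _PEAK_HEIGHT_FLOOR * dens.max()]
    if peaks.size == 0:  # monotone density: fall back to the global argmax
        return float(grid[int(np.argmax(dens))])
    return float(grid[peaks[0]])


def is_normalised(table: pd.DataFrame) -> bool:
    return all(c in table.columns for c in NORM_COLUMNS)


def normalize_population(raw: pd.DataFrame, reference: pd.DataFrame,
                         min_reference: int = 50) -> pd.DataFrame:
    """Normalise intensities against an untreated reference population.

    DNA, EdU and p21 columns are divided by the first-peak location of the
    corresponding reference distribution (the reference 2N/negative mode
    maps to 1); area is divided by the reference median area. The operation
    is invariant to any global multiplicative gain applied to both tables.
    """
    for col in ("dna", "edu", "p21", "area"):
        if col not in raw.columns or col not in reference.columns:
            raise ValueError(f"missing feature column {col!r}")
    if len(reference) < min_reference:
        raise ValueError(
            f"reference population too small for peak estimation "
            f"({len(reference)} < {min_reference})"
        )
    peaks = {col: find_first_peak(reference[col].to_numpy())
             for col in ("dna", "edu", "p21")}
    for col, loc in peaks.items():
        if loc <= 0:
            raise ValueError(f"non-positive first peak for {col!r}")
    med_area = float(reference["area"].median())
    log.info("normalisation factors: %s, median area %.4g", peaks, med_area)

    out = raw.copy()
    out["dna_norm"] = out["dna"] / peaks["dna"]
    out["edu_norm"] = out["edu"] / peaks["edu"]
    out["p21_norm"] = out["p21"] / peaks["p21"]
    out["area_norm"] = out["area"] / med_area
    return out


def classify_cells(normalised: pd.DataFrame,
                   gates: GateConfig | None = None) -> pd.DataFrame:
    """Label each cell with a cell-cycle class and p21/multinucleation flags.

    EdU positivity takes precedence: an EdU+ cell is S whatever its DNA
    content (a replicating polyploid cell is still replicating). Non-S cells
    are 2N below ``t_2n4n``, 4N in [t_2n4n, t_4n8n) and 8N+ above.
    """
    if not is_normalised(normalised):
        raise ValueError("classify_cells requires a normalised table "
                         "(missing *_norm columns)")
    gates = gates or GateConfig()
    out = normalised.copy()
    dna = out["dna_norm"].to_numpy()
    s = out["edu_norm"].to_numpy() >= gates.edu_pos
    cls = np.where(
        s, "S",
        np.where(dna < gates.t_2n4n, "2N",
                 np.where(dna < gates.t_4n8n, "4N", "8N+")),
    )
    out["cc_class"] = cls
    out["p21_pos"] = out["p21_norm"].to_numpy() >= gates.p21_pos
    out["multinucleated"] = out["nuclei"].to_numpy() >= gates.min_nuclei_multi
    return out


def summarise_population(labelled: pd.DataFrame) -> PopulationSummary:
    """Reduce a labelled table to class percentages and population medians."""
    if len(labelled) == 0:
        raise ValueError("empty table")
    for col in ("cc_class", "p21_pos", "multinucleated"):
        if col not in labelled.columns:
            raise ValueError("table must be labelled by classify_cells first")
    n = len(labelled)
    counts = labelled["cc_class"].value_counts()
    pct = {c: 100.0 * counts.get(c, 0) / n for c in ("2N", "S", "4N", "8N+")}
    return PopulationSummary(
        pct_2n=pct["2N"],
        pct_s=pct["S"],
        pct_4n=pct["4N"],
        pct_8n=pct["8N+"],
        pct_p21_pos=100.0 * labelled["p21_pos"].mean(),
        pct_multinucleated=100.0 * labelled["multinucleated"].mean(),
        median_area_norm=float(labelled["area_norm"].median())
        if "area_norm" in labelled.columns else float("nan"),
        n_cells=n,
    )
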