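"""Synthetic data generators with stored ground truth.

Every input type the pipeline consumes can be generated here: per-cell
feature tables with dose-dependent ploidy shifts, colony-count dose-response
series, GWL/B55α expression panels obeying a linear ratio model, phosphosite
intensity matrices with spiked differential sites carrying a +1-proline motif
bias, and tumour/normal expression cohorts. Each generator takes an explicit
seed and returns the data together with a :class:`GroundTruth` record rich
enough to compute expected values of the downstream statistics by brute
force.

Generation starts at the per-cell feature level: no images, no segmentation,
no raw MS spectra.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .doseresp import FourPL

CLASSES = ("2N", "S", "4N", "8N+")

# relative DNA-content medians (genome equivalents) per class
_PLOIDY_MEDIAN = {"2N": 1.0, "4N": 2.0, "8N+": 4.0}
# cell-area scaling per class, relative to a 2N cell
_AREA_FACTOR = {"2N": 1.0, "S": 1.5, "4N": 2.0, "8N+": 4.0}
_BASE_AREA = 500.0  # arbitrary units (pixel^2-like) for an untreated 2N cell

_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def _cv_sigma(cv: float) -> float:
    """Lognormal shape parameter giving coefficient of variation ``cv``."""
    return float(np.sqrt(np.log1p(cv * cv)))


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, FourPL):
        return {"slope": o.slope, "lower": o.lower, "upper": o.upper,
                "midpoint": o.midpoint}
    raise TypeError(f"not JSON serialisable: {type(o)}")


@dataclass
class GroundTruth:
    """Generative truth serialised next to every synthetic dataset."""

    kind: str
    payload: dict

    def save(self, path) -> None:
        Path(path).write_text(
            json.dumps({"kind": self.kind, "payload": self.payload},
                       default=_json_default, indent=1)
        )

    @classmethod
    def load(cls, path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(kind=d["kind"], payload=d["payload"])


def _as_dose_fn(value) -> Callable[[float], float]:
    if callable(value):
        return value
    return lambda dose, v=float(value): v


@dataclass
class PopulationSpec:
    """Conditions for one simulated cell population.

    ``effect_curve`` maps dose (µM) to the fraction of would-be {2N, S}
    cells shifted into {4N, 8N+}; ``p21_fraction`` and
    ``multinucleation_fraction`` may be constants or callables of dose.
    ``intensity_gain`` is an arbitrary-unit gain multiplying all raw
    intensities, so the first-peak normalisation stage has real work to do.
    """

    n_cells: int
    baseline_class_probs: Sequence[float] = (0.5, 0.2, 0.2, 0.1)
    dose: float = 0.0
    effect_curve: FourPL | None = None
    p21_fraction: float | Callable[[float], float] = 0.05
    multinucleation_fraction: float | Callable[[float], float] = 0.02
    intensity_gain: float = 1.0
    peak_cv: float = 0.10
    seed: int = 0
    condition: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        p = np.asarray(self.baseline_class_probs, dtype=float)
        if p.shape != (4,) or np.any(p < 0) or np.any(p > 1) or abs(p.sum() - 1) > 1e-9:
            raise ValueError("baseline_class_probs must be 4 probabilities summing to 1")
        if self.intensity_gain <= 0:
            raise ValueError("intensity_gain must be positive")
        if self.peak_cv < 0:
            raise ValueError("peak_cv must be non-negative")
        if self.dose < 0:
            raise ValueError("dose must be non-negative")

    def class_probs_at_dose(self) -> np.ndarray:
        """Dose-adjusted class probabilities.

        A fraction f(dose) of the baseline {2N, S} mass moves into
        {4N, 8N+}, split in proportion to their baseline probabilities
        (evenly when both are zero), so expected class fractions — and hence
        the expected Euclidean response profile — have a closed form.
        """
        p2, ps, p4, p8 = np.asarray(self.baseline_class_probs, dtype=float)
        f = 0.0
        if self.effect_curve is not None:
            f = float(np.clip(self.effect_curve(self.dose), 0.0, 1.0))
        moved = f * (p2 + ps)
        if p4 + p8 > 0:
            w4, w8 = p4 / (p4 + p8), p8 / (p4 + p8)
        else:
            w4 = w8 = 0.5
        out = np.array([p2 * (1 - f), ps * (1 - f), p4 + moved * w4, p8 + moved * w8])
        return out / out.sum()


def gen_cell_population(spec: PopulationSpec) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a per-cell feature table from a :class:`PopulationSpec`.

    Features mimic the statistical shape of high-content readouts:

    - integrated DNA intensity: lognormal, median ``gain x {1, 2, 4}`` for
      2N/4N/8N+ with CV ``peak_cv``; S cells uniform between the 2N and 4N
      medians;
    - mean EdU intensity: bimodal lognormal (low for non-S, ~10x for S);
    - mean p21 intensity: bimodal lognormal with a ~5x elevated component
      for the p21+ fraction;
    - nuclear count 1, except multinucleated cells (2-4 nuclei);
    - cell area: lognormal, scaled by ploidy class.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cells
    g = spec.intensity_gain
    sig = _cv_sigma(spec.peak_cv)

    probs = spec.class_probs_at_dose()
    labels = rng.choice(len(CLASSES), size=n, p=probs)
    cls = np.array(CLASSES, dtype=object)[labels]

    dna = np.empty(n)
    for name, med in _PLOIDY_MEDIAN.items():
        m = cls == name
        dna[m] = rng.lognormal(np.log(g * med), sig, m.sum())
    s_mask = cls == "S"
    dna[s_mask] = rng.uniform(g * 1.0, g * 2.0, s_mask.sum())

    edu = rng.lognormal(np.log(g * 1.0), sig, n)
    edu[s_mask] = rng.lognormal(np.log(g * 10.0), sig, s_mask.sum())

    p21_frac = float(np.clip(_as_dose_fn(spec.p21_fraction)(spec.dose), 0, 1))
    p21_pos = rng.random(n) < p21_frac
    p21 = rng.lognormal(np.log(g * 1.0), sig, n)
    p21[p21_pos] = rng.lognormal(np.log(g * 5.0), sig, p21_pos.sum())

    mult_frac = float(np.clip(_as_dose_fn(spec.multinucleation_fraction)(spec.dose), 0, 1))
    multi = rng.random(n) < mult_frac
    nuclei = np.ones(n, dtype=int)
    nuclei[multi] = rng.integers(2, 5, multi.sum())

    area_factor = np.array([_AREA_FACTOR[c] for c in cls])
    area = rng.lognormal(np.log(_BASE_AREA * area_factor), _cv_sigma(0.3))

    table = pd.DataFrame(
        {
            "condition": spec.condition,
            "dose_um": spec.dose,
            "dna": dna,
            "edu": edu,
            "p21": p21,
            "area": area,
            "nuclei": nuclei,
        }
    )
    truth = GroundTruth(
        kind="cell_population",
        payload={
            "true_class": cls.tolist(),
            "class_probs": probs,
            "p21_positive": p21_pos,
            "multinucleated": multi,
            "p21_fraction": p21_frac,
            "multinucleation_fraction": mult_frac,
            "intensity_gain": g,
            "peak_cv": spec.peak_cv,
            "dose_um": spec.dose,
            "seed": spec.seed,
        },
    )
    return table, truth


def gen_dose_response(
    truth: FourPL,
    doses: Sequence[float],
    replicates: int,
    noise_cv: float,
    seed: int,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Colony-count-like responses: 4PL(dose) x mean-one lognormal noise."""
    doses = np.asarray(doses, dtype=float)
    if np.any(doses < 0):
        raise ValueError("doses must be non-negative")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    rng = np.random.default_rng(seed)
    sig = _cv_sigma(noise_cv)
    rows = []
    expected = truth(doses)
    for rep in range(1, replicates + 1):
        noise = rng.lognormal(-0.5 * sig * sig, sig, doses.size) if noise_cv > 0 else 1.0
        rows.append(pd.DataFrame({"dose": doses, "response": expected * noise,
                                  "replicate": rep}))
    table = pd.concat(rows, ignore_index=True)
    gt = GroundTruth(
        kind="dose_response",
        payload={"fourpl": truth, "noise_cv": noise_cv, "seed": seed,
                 "doses": doses},
    )
    return table, gt


def gen_expression_panel(
    n_lines: int,
    gradient: float,
    intercept: float,
    noise_sd: float,
    seed: int,
    ed50_floor: float = 0.01,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Scaled GWL/B55α expression panel whose ED50s follow a linear ratio model.

    Scaled expressions are uniform on [0.2, 1]; ED50 = gradient x GWL/B55α +
    intercept + N(0, noise_sd), truncated at ``ed50_floor`` µM.
    """
    if n_lines < 3:
        raise ValueError("need at least 3 lines")
    rng = np.random.default_rng(seed)
    gwl = rng.uniform(0.2, 1.0, n_lines)
    b55a = rng.uniform(0.2, 1.0, n_lines)
    ratio = gwl / b55a
    ed50 = gradient * ratio + intercept + rng.normal(0.0, noise_sd, n_lines)
    ed50 = np.maximum(ed50, ed50_floor)
    panel = pd.DataFrame(
        {
            "line": [f"LINE{i:02d}" for i in range(1, n_lines + 1)],
            "gwl": gwl,
            "b55a": b55a,
            "ed50_um": ed50,
        }
    )
    gt = GroundTruth(
        kind="expression_panel",
        payload={"gradient": gradient, "intercept": intercept,
                 "noise_sd": noise_sd, "ed50_floor": ed50_floor, "seed": seed},
    )
    return panel, gt


def _random_window(rng, plus1_pro_prob: float) -> str:
    """15-mer window centred on a phosphoresidue (S/T), position +1 biased
    towards proline with the given probability."""
    res = rng.choice(list(_AMINO_ACIDS), size=15)
    res[7] = "S" if rng.random() < 0.75 else "T"
    if rng.random() < plus1_pro_prob:
        res[8] = "P"
    elif res[8] == "P":  # resample a non-proline so the probability is exact
        res[8] = rng.choice([a for a in _AMINO_ACIDS if a != "P"])
    return "".join(res)


def gen_phospho_dataset(
    n_sites: int,
    replicates: int = 3,
    frac_down: float = 0.1,
    frac_up: float = 0.05,
    effect_log2: float = 3.0,
    pro_plus1_hit: float = 0.6,
    pro_plus1_bg: float = 0.2,
    missing_rate: float = 0.05,
    seed: int = 0,
    group_names: tuple[str, str] = ("control", "treated"),
) -> tuple[pd.DataFrame, dict, GroundTruth]:
    """Phosphosite intensity matrix (sites x samples) with spiked effects.

    Per-site log2 abundances are Gaussian around a site baseline with
    residual SDs drawn from a scaled inverse-chi-square distribution (prior
    df 4, scale 0.25), the hierarchical model the moderated t-test assumes.
    ``frac_down`` of sites are dephosphorylated in the second group by
    ``effect_log2`` (and ``frac_up`` hyper-phosphorylated); down-regulated
    sites carry proline at window position +1 with probability
    ``pro_plus1_hit``, all other sites with ``pro_plus1_bg``. A
    ``missing_rate`` fraction of intensities is zeroed to exercise
    imputation. Returns (matrix, design, truth); design maps sample name to
    group.
    """
    if frac_down < 0 or frac_up < 0 or frac_down + frac_up > 1:
        raise ValueError("invalid down/up fractions")
    if replicates < 2:
        raise ValueError("need at least 2 replicates per group")
    rng = np.random.default_rng(seed)

    n_down = int(round(frac_down * n_sites))
    n_up = int(round(frac_up * n_sites))
    status = np.array(["ns"] * n_sites, dtype=object)
    status[:n_down] = "down"
    status[n_down:n_down + n_up] = "up"
    rng.shuffle(status)

    base = rng.normal(20.0, 2.0, n_sites)
    prior_df, prior_scale = 4.0, 0.25
    site_sd = np.sqrt(prior_df * prior_scale**2 / rng.chisquare(prior_df, n_sites))

    shift = np.where(status == "down", -effect_log2,
                     np.where(status == "up", effect_log2, 0.0))

    samples = [f"{group_names[0]}_{i+1}" for i in range(replicates)] + [
        f"{group_names[1]}_{i+1}" for i in range(replicates)
    ]
    design = {s: (group_names[0] if i < replicates else group_names[1])
              for i, s in enumerate(samples)}

    log2 = np.empty((n_sites, 2 * replicates))
    for j in range(2 * replicates):
        mu = base + (shift if j >= replicates else 0.0)
        log2[:, j] = rng.normal(mu, site_sd)
    intensity = np.exp2(log2)
    if missing_rate > 0:
        intensity[rng.random(intensity.shape) < missing_rate] = 0.0

    windows = [
        _random_window(rng, pro_plus1_hit if status[i] == "down" else pro_plus1_bg)
        for i in range(n_sites)
    ]
    site_ids = [f"PROT{i:05d}_{windows[i][7]}{100 + i}" for i in range(n_sites)]

    matrix = pd.DataFrame(intensity, index=pd.Index(site_ids, name="site"),
                          columns=samples)
    matrix.insert(0, "window", windows)

    gt = GroundTruth(
        kind="phospho",
        payload={
            "status": status.tolist(),
            "site_ids": site_ids,
            "effect_log2": effect_log2,
            "frac_down": frac_down,
            "frac_up": frac_up,
            "pro_plus1_hit": pro_plus1_hit,
            "pro_plus1_bg": pro_plus1_bg,
            "missing_rate": missing_rate,
            "seed": seed,
        },
    )
    return matrix, design, gt


def gen_cohort_expression(
    groups: Sequence[tuple[str, int, int]],
    shift_log: Mapping[str, Mapping[str, float]] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Tumour/normal FPKM-like cohort for the B55α/GWL genes.

    ``groups`` lists (name, n_tumour, n_normal); ``n_normal`` may be 0,
    emulating cohorts without matched normal tissue ("nd"). ``shift_log``
    maps group -> gene -> additive shift on the natural-log scale applied to
    tumour samples. Genes are keyed ``"b55a"`` and ``"gwl"`` with baseline
    log-medians ln(20) and ln(5) FPKM.
    """
    shift_log = shift_log or {}
    rng = np.random.default_rng(seed)
    base_mu = {"b55a": np.log(20.0), "gwl": np.log(5.0)}
    sigma = 0.6
    rows = []
    for name, n_t, n_n in groups:
        if n_t < 0 or n_n < 0:
            raise ValueError("sample counts must be non-negative")
        for gene in ("b55a", "gwl"):
            sh = float(shift_log.get(name, {}).get(gene, 0.0))
            for i in range(n_t):
                rows.append((name, "tumour", f"{name}_T{i+1}", gene,
                             float(np.exp(rng.normal(base_mu[gene] + sh, sigma)))))
            for i in range(n_n):
                rows.append((name, "normal", f"{name}_N{i+1}", gene,
                             float(np.exp(rng.normal(base_mu[gene], sigma)))))
    table = pd.DataFrame(rows, columns=["group", "tissue", "sample", "gene", "fpkm"])
    gt = GroundTruth(
        kind="cohort",
        payload={"groups": [list(g) for g in groups],
                 "shift_log": {k: dict(v) for k, v in shift_log.items()},
                 "sigma": sigma, "seed": seed},
    )
    return table, gt
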