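"""End-to-end orchestration: curate → fit → evidence → modality → report.

The central product is the classification grid: one cell per
(step type, parameter, dataset origin) combination, labelled

* ``M1/U``  — uninormal supported (unimodal by definition),
* ``M2/U``  — binormal supported but the components overlap enough that
  the density stays unimodal (a single set of weighted moments and a
  harmonic elastic model remain valid),
* ``M2/B``  — binormal and genuinely bimodal (polymorphism; the two-state
  elastic model applies),
* ``IE``    — insufficient evidence either way.

Each cell is classified independently against the fixed 0.95/0.05
evidence thresholds; no multiple-testing correction is applied.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import io as hio
from .io import HelicalEnsemble, PARAMETERS, STEP_TYPES, filter_outliers, subsample
from .mixture import evidence, DegenerateFitError
from .modality import is_bimodal, weighted_stats

logger = logging.getLogger("helimodal")


@dataclass
class ClassificationCell:
    """Classification outcome for one (step_type, parameter, origin) ensemble."""

    step_type: str
    parameter: str
    origin: str
    n: int
    label: str  # M1/U, M2/U, M2/B, IE, or "failed"
    p_m2: float | None = None
    bic1: float | None = None
    bic2: float | None = None
    # modality fields, populated only for M2 cells
    r: float | None = None
    s_r: float | None = None
    separation: float | None = None
    threshold: float | None = None
    weighted_mean: float | None = None
    weighted_sd: float | None = None
    # mixture parameters (ascending-mean order)
    mu1: float | None = None
    sigma1: float | None = None
    mu2: float | None = None
    sigma2: float | None = None
    p_r: float | None = None
    error: str | None = None


_ORIGIN_ORDER = {o: i for i, o in enumerate(hio.ORIGINS)}
_STEP_ORDER = {s: i for i, s in enumerate(STEP_TYPES)}
_PARAM_ORDER = {p: i for i, p in enumerate(PARAMETERS)}


def _cell_sort_key(c: ClassificationCell) -> tuple[int, int, int]:
    return (_STEP_ORDER[c.step_type], _PARAM_ORDER[c.parameter],
            _ORIGIN_ORDER[c.origin])


def classify_all(
    dataset: Iterable[HelicalEnsemble],
    config: Mapping[str, object] | None = None,
) -> tuple[list[ClassificationCell], dict]:
    """Classify every ensemble; per-cell failures never abort the grid.

    Config keys (all optional): ``k_sd`` (outlier cut in SDs, default 3),
    ``filter_origins`` (origins the outlier cut applies to; default the
    X-ray origins only), ``subsample_m`` and ``seed`` (random curation
    subsample), ``n_restarts``, ``fit_range``, ``hi``/``lo`` evidence
    thresholds.

    Returns the ordered cell list and summary fractions (overall and
    per-origin fraction of M2 cells among classified, and fraction B among
    M2).
    """
    cfg = dict(config or {})
    k_sd = float(cfg.get("k_sd", 3.0))
    filter_origins = set(cfg.get("filter_origins",
                                 ("xray_naked", "xray_protein", "xray_intercalator")))
    sub_m = cfg.get("subsample_m")
    seed = int(cfg.get("seed", 0))
    n_restarts = int(cfg.get("n_restarts", 4))
    fit_range = cfg.get("fit_range")
    hi = float(cfg.get("hi", 0.95))
    lo = float(cfg.get("lo", 0.05))

    cells: list[ClassificationCell] = []
    for ens in dataset:
        cell = ClassificationCell(step_type=ens.step_type, parameter=ens.parameter,
                                  origin=ens.origin, n=ens.n, label="failed")
        try:
            cur = ens
            if k_sd > 0 and ens.origin in filter_origins and ens.n >= 2:
                cur, _ = filter_outliers(cur, k_sd=k_sd)
            if sub_m is not None:
                cur = subsample(cur, int(sub_m), seed=seed)
            cell.n = cur.n
            ev = evidence(cur, n_restarts=n_restarts, seed=seed,
                          fit_range=fit_range, hi=hi, lo=lo)
            cell.p_m2, cell.bic1, cell.bic2 = ev.p_m2, ev.bic1, ev.bic2
            m = ev.fit2.model
            cell.mu1, cell.sigma1 = m.mu1, m.sigma1
            cell.mu2, cell.sigma2 = m.mu2, m.sigma2
            cell.p_r = m.p_r
            if ev.label == "M1":
                cell.label = "M1/U"
            elif ev.label == "IE":
                cell.label = "IE"
            else:  # M2: the Helguero test decides modality
                mod = is_bimodal(m)
                cell.r, cell.s_r = mod.r, mod.s_r
                cell.separation, cell.threshold = mod.separation, mod.threshold
                cell.label = f"M2/{mod.label}"
                if mod.label == "U":
                    cell.weighted_mean, cell.weighted_sd = weighted_stats(m)
        except (ValueError, DegenerateFitError) as exc:
            cell.error = str(exc)
            logger.warning("cell %s/%s/%s failed: %s", ens.step_type,
                           ens.parameter, ens.origin, exc)
        cells.append(cell)
    cells.sort(key=_cell_sort_key)
    summary = summarize_grid(cells)
    return cells, summary


def summarize_grid(cells: list[ClassificationCell]) -> dict:
    """Pooled and per-origin fractions of binormal (M2) and bimodal cells."""
    def frac(sub: list[ClassificationCell]) -> dict:
        classified = [c for c in sub if c.label in ("M1/U", "M2/U", "M2/B", "IE")]
        m2 = [c for c in classified if c.label.startswith("M2")]
        b = [c for c in m2 if c.label == "M2/B"]
        return {
            "n_cells": len(sub),
            "n_classified": len(classified),
            "fraction_m2": len(m2) / len(classified) if classified else float("nan"),
            "fraction_b_of_m2": len(b) / len(m2) if m2 else float("nan"),
        }

    out = {"pooled": frac(cells), "per_origin": {}}
    for origin in sorted({c.origin for c in cells}, key=_ORIGIN_ORDER.get):
        out["per_origin"][origin] = frac([c for c in cells if c.origin == origin])
    return out


def grid_to_frame(cells: list[ClassificationCell]) -> pd.DataFrame:
    """Classification grid as a tidy DataFrame in canonical order."""
    return pd.DataFrame([asdict(c) for c in cells])


def correlation_report(
    joint: Mapping[tuple[str, str], np.ndarray] | np.ndarray,
    parameters: tuple[str, ...] = PARAMETERS,
) -> pd.DataFrame:
    """Pearson correlations between helical parameters per (step, origin).

    ``joint`` maps (step_type, origin) to an (n, 6) array of joint
    snapshots (a bare array is treated as a single anonymous group).
    Constant columns yield undefined correlations, reported as NaN.
    """
    if isinstance(joint, np.ndarray):
        joint = {("NA", "NA"): joint}
    rows = []
    for (step, origin), arr in joint.items():
        arr = np.atleast_2d(np.asarray(arr, dtype=float))
        d = arr.shape[1]
        sd = arr.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(arr, rowvar=False)
        corr = np.atleast_2d(corr)
        for i in range(d):
            for j in range(i + 1, d):
                val = corr[i, j]
                if sd[i] == 0 or sd[j] == 0:
                    val = float("nan")
                rows.append((step, origin, parameters[i], parameters[j], val))
    return pd.DataFrame(rows, columns=["step_type", "origin",
                                       "parameter_i", "parameter_j", "pearson_r"])


_KNOWN_SECTIONS = {"io", "curation", "fitting", "thresholds", "energy",
                   "dynamics", "simulate"}


def run_config(config: Mapping[str, object] | str | Path,
               out_dir: str | Path = ".") -> dict:
    """Run the full pipeline from a config mapping (or YAML file path).

    Sections: ``io`` (input table path and dialect), ``simulate``
    (self-contained mode: scenario specs to generate before classifying),
    ``curation`` (k_sd, filter_origins, subsample_m, seed), ``fitting``
    (n_restarts, seed, fit_range), ``thresholds`` (hi, lo), ``dynamics``
    (windows for a time series input). All randomness is seeded through
    the config, so identical configs give byte-identical outputs.

    Writes grid.tsv, summary.json, fits.json and (for time-series input)
    kinetics.json under ``out_dir``; returns the report bundle as a dict.
    """
    if isinstance(config, (str, Path)):
        import yaml

        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = dict(config or {})
    unknown = set(cfg) - _KNOWN_SECTIONS
    if unknown:
        raise ValueError(f"unknown config section(s): {sorted(unknown)}")
    out_dir = Path(out_dir)

    io_cfg = dict(cfg.get("io", {}) or {})
    sim_cfg = dict(cfg.get("simulate", {}) or {})
    ensembles: list[HelicalEnsemble] = []
    if io_cfg.get("input"):
        path = Path(io_cfg["input"])
        if not path.exists():
            raise FileNotFoundError(f"input table not found: {path}")
        ensembles.extend(hio.read_table(path, dialect=io_cfg.get("dialect", "tsv"),
                                        ser_config=io_cfg.get("ser_config")))
    if sim_cfg:
        ensembles.extend(_simulate_from_config(sim_cfg))
    if not ensembles:
        raise ValueError("config provides neither io.input nor a simulate block")

    clf_cfg = {**dict(cfg.get("curation", {}) or {}),
               **dict(cfg.get("fitting", {}) or {}),
               **dict(cfg.get("thresholds", {}) or {})}
    cells, summary = classify_all(ensembles, clf_cfg)

    out_dir.mkdir(parents=True, exist_ok=True)
    frame = grid_to_frame(cells)
    num_cols = frame.select_dtypes(include=[float]).columns
    frame[num_cols] = frame[num_cols].map(
        lambda v: float(f"{v:.6g}") if pd.notna(v) else v)
    frame.to_csv(out_dir / "grid.tsv", sep="\t", index=False)
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    fits = [{k: v for k, v in asdict(c).items() if v is not None} for c in cells]
    with open(out_dir / "fits.json", "w") as fh:
        json.dump(fits, fh, indent=2)

    bundle = {"cells": cells, "summary": summary}

    dyn_cfg = dict(cfg.get("dynamics", {}) or {})
    series = [e for e in ensembles if e.times is not None and e.n >= 2]
    if dyn_cfg and series:
        from .dynamics import assign_states, transition_stats, convergence_profile
        from .mixture import fit_binormal

        kin = {}
        for ens in series:
            fit = fit_binormal(ens, seed=int(dict(cfg.get("fitting", {}) or {})
                                             .get("seed", 0)))
            traj = assign_states(ens, fit)
            st = transition_stats(traj, min_dwell=int(dyn_cfg.get("min_dwell", 0)))
            entry = {
                "n_transitions": st.n_transitions,
                "rate_per_ns": st.rate_per_ns,
                "mean_residence_ns": list(st.mean_residence),
                "occupancy": list(st.occupancy),
            }
            windows = dyn_cfg.get("windows")
            if windows:
                entry["convergence"] = convergence_profile(ens, fit, windows)
            kin["/".join(ens.key)] = entry
        with open(out_dir / "kinetics.json", "w") as fh:
            json.dump(kin, fh, indent=2)
        bundle["kinetics"] = kin
    return bundle


def _simulate_from_config(sim_cfg: Mapping[str, object]) -> list[HelicalEnsemble]:
    """Generate ensembles for a ``simulate`` config block."""
    from .synthetic import (BinormalSpec, TelegraphSpec, PRESETS,
                            sample_binormal, sample_telegraph)

    out: list[HelicalEnsemble] = []
    seed = int(sim_cfg.get("seed", 0))
    for i, block in enumerate(sim_cfg.get("ensembles", [])):
        b = dict(block)
        preset = b.get("preset")
        if preset:
            spec = PRESETS[preset]
        else:
            spec = BinormalSpec(mu1=float(b["mu1"]), sigma1=float(b["sigma1"]),
                                mu2=float(b["mu2"]), sigma2=float(b["sigma2"]),
                                p_r=float(b["p_r"]))
        kind = b.get("kind", "binormal")
        common = {k: b[k] for k in ("step_type", "parameter", "origin") if k in b}
        if kind == "binormal":
            out.append(sample_binormal(spec, n=int(b.get("n", 10000)),
                                       seed=seed + i, **common))
        elif kind == "telegraph":
            tspec = TelegraphSpec(rate_12=float(b.get("rate_12", 5.0)),
                                  rate_21=float(b.get("rate_21", 5.0)),
                                  emission=spec, dt=float(b.get("dt", 0.001)))
            series, _ = sample_telegraph(tspec,
                                         duration_ns=float(b.get("duration_ns", 10.0)),
                                         seed=seed + i, **common)
            out.append(series)
        else:
            raise ValueError(f"unknown simulate kind {kind!r}")
    return out
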