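"""Config-driven orchestration of the full quantification chain.

Stages run in order: simulate -> fit -> graphical -> select -> quant ->
stats -> report.  Every stage writes its artifacts (CSV/JSON) into the
output directory and later stages re-read them, so re-running a stage from
cached upstream artifacts is idempotent.  All randomness flows from the
config seed; the report records a config hash for provenance.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import (StudyMeta, TimeActivityCurve, read_tac_table, to_suv,
                   write_tac_table)
from .graphical import logan_vt, patlak_ki
from .imaging import compute_tbr
from .input_function import build_input_function
from .kinetic import FitOptions, fit_compartment
from .selection import select_model
from .simulate import default_spec, generate_study
from .stats import pearson_matrix, welch_t

STAGES = ("simulate", "fit", "graphical", "select", "quant", "stats", "report")


class PipelineError(RuntimeError):
    """A stage failed; the stage name prefixes the message."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one cohort analysis."""

    tracer: str = "rhPSMA73"
    day: int = 28
    seed: int = 0
    out_dir: str = "petkin_out"
    noise_scale: float = 0.0
    jitter_sd: float = 0.0
    n_animals: int | None = None
    models: tuple = ("1TCM", "2TCM")
    weighting: str = "uniform"
    multistart_count: int = 20
    fit_vB: bool = False
    tstar: float | str = 20.0
    max_rel_dev: float = 0.10
    mtv_fraction: float | None = None      # default per tracer
    tbr_at: float | None = None            # minutes; default: last midpoint
    contrasts: tuple = (("tumor", "brain", "K1"), ("tumor", "brain", "VT"))
    plots: bool = True

    def __post_init__(self):
        if not self.models:
            raise ValueError("model list must not be empty")
        for m in self.models:
            if m not in ("1TCM", "2TCM"):
                raise ValueError(f"unknown model {m!r}")
        if self.mtv_fraction is None:
            self.mtv_fraction = 0.75 if self.tracer == "rhPSMA73" else 0.50
        if not 0 < self.mtv_fraction < 1:
            raise ValueError("mtv_fraction must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("models", "contrasts"):
            if key in raw:
                raw[key] = tuple(tuple(x) if isinstance(x, list) else x
                                 for x in raw[key]) if key == "contrasts" \
                    else tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def fit_options(self) -> FitOptions:
        return FitOptions(weighting=self.weighting,
                          multistart_count=self.multistart_count,
                          seed=self.seed, fit_vB=self.fit_vB)


def _spec_for(config: PipelineConfig):
    spec = default_spec(config.tracer, config.day,
                        noise_scale=config.noise_scale,
                        jitter_sd=config.jitter_sd)
    if config.n_animals is not None:
        spec = dataclasses.replace(spec, n_animals=config.n_animals)
    return spec


def _out(config) -> Path:
    p = Path(config.out_dir)
    p.mkdir(parents=True, exist_ok=True)
    return p


# -- stage: simulate --------------------------------------------------------

def stage_simulate(config: PipelineConfig) -> None:
    out = _out(config) / "study"
    spec = _spec_for(config)
    study = generate_study(spec, seed=config.seed)
    for entry in study.animals:
        meta: StudyMeta = entry["meta"]
        tacs = [entry[r] for r in spec.regions]
        write_tac_table(tacs, out / f"tac_{meta.animal_id}.csv")
    study.truth.to_csv(out / "truth.csv", index=False)
    manifest = {
        "tracer": spec.tracer, "day": spec.day, "seed": config.seed,
        "n_animals": spec.n_animals, "noise_scale": spec.noise.scale,
        "jitter_sd": spec.jitter_sd,
        "injected_dose_kbq": spec.injected_dose_kbq,
        "body_weight_g": spec.body_weight_g,
        "animals": [e["meta"].animal_id for e in study.animals],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _load_study(config: PipelineConfig):
    out = _out(config) / "study"
    manifest_path = out / "manifest.json"
    if not manifest_path.exists():
        raise PipelineError("fit", "no simulated study found; run simulate first")
    manifest = json.loads(manifest_path.read_text())
    animals = []
    for animal_id in manifest["animals"]:
        tacs = {t.roi_label: t for t in read_tac_table(out / f"tac_{animal_id}.csv")}
        tacs["meta"] = StudyMeta(manifest["tracer"], manifest["injected_dose_kbq"],
                                 manifest["body_weight_g"], manifest["day"],
                                 animal_id)
        animals.append(tacs)
    return manifest, animals


def _input_for(config: PipelineConfig, blood: TimeActivityCurve):
    spec = _spec_for(config)
    return build_input_function(blood, spec.pbr, spec.parent_fraction)


# -- stage: fit -------------------------------------------------------------

def stage_fit(config: PipelineConfig) -> None:
    manifest, animals = _load_study(config)
    options = config.fit_options()
    records = []
    for entry in animals:
        blood = entry["vena_cava"]
        inp = _input_for(config, blood)
        for region in ("tumor", "brain"):
            for model in config.models:
                fit = fit_compartment(entry[region], inp, blood, model, options)
                rec = {"animal_id": entry["meta"].animal_id, "region": region,
                       **fit.to_dict()}
                records.append(rec)
    (_out(config) / "fits.json").write_text(json.dumps(records, indent=2))
    flat = [{"animal_id": r["animal_id"], "region": r["region"],
             "model": r["model"], **r["params"],
             **{k: v for k, v in r["derived"].items()},
             "sswres": r["sswres"], "aic": r["aic"], "sc": r["sc"],
             "msc": r["msc"], "converged": r["converged"]} for r in records]
    pd.DataFrame(flat).to_csv(_out(config) / "fits.csv", index=False)


# -- stage: graphical -------------------------------------------------------

def stage_graphical(config: PipelineConfig) -> None:
    manifest, animals = _load_study(config)
    rows = []
    for entry in animals:
        inp = _input_for(config, entry["vena_cava"])
        for region in ("tumor", "brain"):
            for method, fn in (("logan", logan_vt), ("patlak", patlak_ki)):
                res = fn(entry[region], inp, tstar=config.tstar,
                         max_rel_dev=config.max_rel_dev)
                rows.append({"animal_id": entry["meta"].animal_id,
                             "region": region, **res.to_dict()})
    pd.DataFrame(rows).to_csv(_out(config) / "graphical.csv", index=False)


# -- stage: select ----------------------------------------------------------

def stage_select(config: PipelineConfig) -> None:
    fits_path = _out(config) / "fits.json"
    if not fits_path.exists():
        raise PipelineError("select", "fits.json missing; run fit first")
    records = json.loads(fits_path.read_text())

    class _F:     # lightweight stand-in so select_model can consume the records
        def __init__(self, r):
            self.model, self.aic, self.sc, self.msc = r["model"], r["aic"], r["sc"], r["msc"]
            self.sswres, self.p, self.converged = r["sswres"], r["p"], r["converged"]

    report = {}
    keys = sorted({(r["animal_id"], r["region"]) for r in records})
    winners: dict[str, list] = {}
    for animal_id, region in keys:
        group = [_F(r) for r in records
                 if r["animal_id"] == animal_id and r["region"] == region]
        if len([f for f in group if f.converged]) < 2:
            continue
        sel = select_model(group)
        report[f"{animal_id}/{region}"] = sel.to_dict()
        winners.setdefault(region, []).append(sel.winner)
    report["winner_counts"] = {
        region: {m: ws.count(m) for m in sorted(set(ws))}
        for region, ws in winners.items()}
    (_out(config) / "selection.json").write_text(json.dumps(report, indent=2))


# -- stage: quant -----------------------------------------------------------

def stage_quant(config: PipelineConfig) -> None:
    manifest, animals = _load_study(config)
    rows = []
    for entry in animals:
        meta = entry["meta"]
        at = config.tbr_at or float(entry["tumor"].midpoints[-1])
        tbr = compute_tbr(entry["tumor"], entry["brain"], at=at)
        suv_t = to_suv(entry["tumor"], meta)
        suv_b = to_suv(entry["brain"], meta)
        rows.append({"animal_id": meta.animal_id, "tbr_at_min": at, "tbr": tbr,
                     "suvmean_tumor_last": float(suv_t.values[-1]),
                     "suvmean_brain_last": float(suv_b.values[-1]),
                     "suvmean_tumor_peak": float(suv_t.values.max())})
    pd.DataFrame(rows).to_csv(_out(config) / "quant.csv", index=False)


# -- stage: stats -----------------------------------------------------------

def stage_stats(config: PipelineConfig) -> None:
    fits_path = _out(config) / "fits.csv"
    if not fits_path.exists():
        raise PipelineError("stats", "fits.csv missing; run fit first")
    fits = pd.read_csv(fits_path)
    best_model = "2TCM" if "2TCM" in config.models else config.models[0]
    df = fits[fits.model == best_model]
    rows = []
    for region_a, region_b, param in config.contrasts:
        a = df[df.region == region_a][param].to_numpy()
        b = df[df.region == region_b][param].to_numpy()
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        if a.size < 2 or b.size < 2:
            continue
        cmp = welch_t(a, b, label_a=f"{region_a}:{param}",
                      label_b=f"{region_b}:{param}")
        rows.append({**cmp.to_dict(), "stars": cmp.stars(), "param": param})
    pd.DataFrame(rows).to_csv(_out(config) / "stats.csv", index=False)
    # Pearson correlation between region mean TACs
    manifest, animals = _load_study(config)
    mean_curves = []
    for region in ("tumor", "brain"):
        vals = np.mean([e[region].values for e in animals], axis=0)
        mean_curves.append(animals[0][region].with_values(vals, roi_label=region))
    r = pearson_matrix(mean_curves)
    pd.DataFrame(r, index=["tumor", "brain"],
                 columns=["tumor", "brain"]).to_csv(_out(config) / "pearson.csv")


# -- stage: report ----------------------------------------------------------

def stage_report(config: PipelineConfig) -> None:
    out = _out(config)
    report = {"petkin_version": __version__, "config_hash": config.config_hash(),
              "seed": config.seed,
              "config": dataclasses.asdict(config)}
    for name in ("selection.json",):
        p = out / name
        if p.exists():
            report[name.split(".")[0]] = json.loads(p.read_text())
    for name in ("fits.csv", "graphical.csv", "quant.csv", "stats.csv"):
        p = out / name
        if p.exists():
            report[name.split(".")[0]] = pd.read_csv(p).to_dict(orient="records")
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    if config.plots:
        _make_plots(config)


def _make_plots(config: PipelineConfig) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    out = _out(config)
    manifest, animals = _load_study(config)
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    for entry in animals:
        meta = entry["meta"]
        for ax, region in zip(axes[:2], ("tumor", "brain")):
            suv = to_suv(entry[region], meta)
            ax.plot(suv.midpoints, suv.values, lw=0.8)
            ax.set_title(f"{config.tracer} {region} (SUVmean)")
            ax.set_xlabel("min")
        inp = _input_for(config, entry["vena_cava"])
        from .graphical import logan_transform
        x, y, _ = logan_transform(entry["tumor"], inp)
        axes[2].plot(x, y, ".", ms=3)
        axes[2].set_title("Logan plot (tumor)")
    fig.tight_layout()
    fig.savefig(out / "diagnostics.png", dpi=110)
    plt.close(fig)


_STAGE_FN = {"simulate": stage_simulate, "fit": stage_fit,
             "graphical": stage_graphical, "select": stage_select,
             "quant": stage_quant, "stats": stage_stats, "report": stage_report}


def run_pipeline(config: PipelineConfig, stages=None) -> dict:
    """Run the requested stages in canonical order; returns the report dict."""
    todo = list(STAGES) if stages in (None, "all") else list(stages)
    for s in todo:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}")
    for s in STAGES:
        if s not in todo:
            continue
        try:
            _STAGE_FN[s](config)
        except PipelineError:
            raise
        except Exception as exc:                 # pragma: no cover - defensive
            raise PipelineError(s, str(exc)) from exc
    report_path = _out(config) / "report.json"
    if report_path.exists():
        return json.loads(report_path.read_text())
    return {}
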