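"""End-to-end reproducible experiments: simulate -> measure -> report.

A pipeline config (YAML or dict) declares a list of stages with per-stage
parameters and a base seed.  Each stage kind plants known ground truth
with the phantom generators, runs the corresponding measurement pipeline,
and reports recovered vs generating values.  Identical config + seed give
identical results; every output directory receives the config, a
provenance record (config hash, seed, package version) and the results.

Bundled recipes (one YAML per quantification) live in
``tracheoquant/recipes`` and are listed by :func:`bundled_recipes`.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import phantoms
from .coloc import ColocParams, per_object_coloc
from .errors import ConfigError
from .image import LandmarkSet, PolylineROI
from .junctions import make_segment, summarize_junctions
from .phantoms import (
    ImagingParams,
    JunctionLatticeParams,
    NucleiFieldParams,
    TubePhantomParams,
    VesicleFieldParams,
)
from .stats import build_report, percent_difference
from .tube import dt_ratio, trace_centerline
from .vesicles import census, classify_cargo, detect_vesicles, count_nuclei

__all__ = ["PipelineConfig", "run_experiment", "bundled_recipes", "load_recipe"]

_IMAGING_KEYS = {
    "pixel_size_um",
    "psf_sigma_um",
    "poisson_noise",
    "read_noise_sigma",
    "bit_depth",
}

STAGE_PARAM_KEYS: dict[str, set[str]] = {
    "straight_ratio": {"length_um"},
    "tube_cohorts": {"groups", "control", "length_um", "diameter_um", "imaging"},
    "vesicle_census": {
        "n_vesicles",
        "p_both",
        "p_ch1_only",
        "p_ch2_only",
        "diameter_um_mean",
        "diameter_um_sd",
        "within_vesicle_overlap",
        "min_separation_um",
        "presence_factor",
        "imaging",
    },
    "coloc_overlap": {
        "n_vesicles",
        "within_vesicle_overlap",
        "diameter_um_mean",
        "diameter_um_sd",
        "min_separation_um",
        "ratio_cutoff",
        "imaging",
    },
    "diameter_recovery": {
        "n_vesicles",
        "diameter_um",
        "diameter_um_sd",
        "min_separation_um",
        "imaging",
    },
    "nuclei_count": {"n_images", "n_nuclei", "nucleus_diameter_um", "imaging"},
    "junction_comparison": {
        "groups",
        "n_cells",
        "orientation_jitter_deg",
        "length_sd_um",
        "imaging",
    },
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    Unknown top-level or per-stage keys are rejected before any work runs.
    """

    name: str
    stages: list[dict]
    seed: int = 0
    pixel_size_um: float = 0.1
    description: str = ""
    log_level: str = "INFO"
    output_dir: str | None = None
    extras: dict = field(default_factory=dict)

    _TOP_KEYS = {
        "name",
        "stages",
        "seed",
        "pixel_size_um",
        "description",
        "log_level",
        "output_dir",
    }

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        if not isinstance(doc, dict):
            raise ConfigError("config must be a mapping")
        unknown = set(doc) - cls._TOP_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "name" not in doc or "stages" not in doc:
            raise ConfigError("config requires 'name' and 'stages'")
        stages = doc["stages"]
        if not isinstance(stages, list) or not stages:
            raise ConfigError("'stages' must be a non-empty list")
        for i, st in enumerate(stages):
            if not isinstance(st, dict) or "kind" not in st:
                raise ConfigError(f"stage {i}: missing 'kind'")
            kind = st["kind"]
            if kind not in STAGE_PARAM_KEYS:
                raise ConfigError(
                    f"stage {i}: unknown kind {kind!r}; "
                    f"known: {sorted(STAGE_PARAM_KEYS)}"
                )
            bad = set(st) - {"kind", "params"}
            if bad:
                raise ConfigError(f"stage {i} ({kind}): unknown keys {sorted(bad)}")
            params = st.get("params", {}) or {}
            bad = set(params) - STAGE_PARAM_KEYS[kind]
            if bad:
                raise ConfigError(
                    f"stage {i} ({kind}): unknown params {sorted(bad)}"
                )
            img = params.get("imaging", {}) or {}
            bad = set(img) - _IMAGING_KEYS
            if bad:
                raise ConfigError(
                    f"stage {i} ({kind}): unknown imaging params {sorted(bad)}"
                )
        return cls(
            name=doc["name"],
            stages=stages,
            seed=int(doc.get("seed", 0)),
            pixel_size_um=float(doc.get("pixel_size_um", 0.1)),
            description=doc.get("description", ""),
            log_level=doc.get("log_level", "INFO"),
            output_dir=doc.get("output_dir"),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        try:
            doc = yaml.safe_load(Path(path).read_text())
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse {path}: {exc}") from exc
        return cls.from_dict(doc)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "description": self.description,
            "seed": self.seed,
            "pixel_size_um": self.pixel_size_um,
            "stages": self.stages,
        }


def _imaging(config: PipelineConfig, params: dict, seed: int) -> ImagingParams:
    over = dict(params.get("imaging", {}) or {})
    over.setdefault("pixel_size_um", config.pixel_size_um)
    return ImagingParams(seed=seed, **over)


def _stage_seeds(base_seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(np.random.SeedSequence(base_seed))
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


# --------------------------------------------------------------------------
# stage runners


def run_straight_ratio(params: dict, imaging: ImagingParams) -> dict:
    """Arc/chord ratio of a perfectly straight two-point traced path."""
    length_um = float(params.get("length_um", 40.0))
    n_px = length_um / imaging.pixel_size_um
    path = PolylineROI([(0.0, 0.0), (n_px, 0.0)], name="straight")
    res = dt_ratio(path, imaging.pixel_size_um)
    return {
        "arc_length_um": res.arc_length_um,
        "chord_length_um": res.chord_length_um,
        "ratio": res.ratio,
    }


def run_tube_cohorts(params: dict, config: PipelineConfig, seed: int) -> dict:
    """Cohorts of tube phantoms: generate, auto-trace, compare group ratios.

    ``groups`` maps group name -> {tortuosity, n}; ``control`` names the
    reference group for the percent difference of mean ratios.
    """
    groups: dict = params["groups"]
    control = params.get("control") or sorted(groups)[0]
    if control not in groups:
        raise ConfigError(f"control group {control!r} not in groups")
    length_um = float(params.get("length_um", 40.0))
    diameter_um = float(params.get("diameter_um", 3.0))

    total = sum(int(g["n"]) for g in groups.values())
    seeds = iter(_stage_seeds(seed, total))
    rows = []
    for gname in sorted(groups):
        spec = groups[gname]
        tort = float(spec["tortuosity"])
        for _ in range(int(spec["n"])):
            imaging = _imaging(config, params, next(seeds))
            img, truth = phantoms.generate_tube(
                TubePhantomParams(
                    length_um=length_um, diameter_um=diameter_um, tortuosity=tort
                ),
                imaging,
            )
            anchors = LandmarkSet(np.asarray(truth.landmarks))
            traced = trace_centerline(img, "lumen", anchors)
            res = dt_ratio(traced, imaging.pixel_size_um)
            rows.append(
                {
                    "group": gname,
                    "ratio": res.ratio,
                    "true_ratio": truth.arc_chord_ratio,
                }
            )
    df = pd.DataFrame(rows)
    report = build_report(df, metrics=["ratio"], control_group=control)
    means = {
        g: float(df.loc[df["group"] == g, "ratio"].mean()) for g in sorted(groups)
    }
    true_means = {
        g: float(df.loc[df["group"] == g, "true_ratio"].mean()) for g in sorted(groups)
    }
    others = [g for g in sorted(groups) if g != control]
    out = {
        "group_mean_ratio": means,
        "group_true_mean_ratio": true_means,
        "report": report.to_dict(),
    }
    if others:
        out["percent_difference_vs_control"] = {
            g: percent_difference(means[control], means[g]) for g in others
        }
        out["generating_percent_difference"] = {
            g: percent_difference(true_means[control], true_means[g]) for g in others
        }
    return out


def run_vesicle_census(params: dict, config: PipelineConfig, seed: int) -> dict:
    """Two-channel vesicle field -> detection -> cargo census."""
    imaging = _imaging(config, params, seed)
    vp = VesicleFieldParams(
        n_vesicles=int(params.get("n_vesicles", 194)),
        p_both=float(params.get("p_both", 0.67)),
        p_ch1_only=float(params.get("p_ch1_only", 0.15)),
        p_ch2_only=float(params.get("p_ch2_only", 0.18)),
        diameter_um_mean=float(params.get("diameter_um_mean", 0.55)),
        diameter_um_sd=float(params.get("diameter_um_sd", 0.05)),
        within_vesicle_overlap=float(params.get("within_vesicle_overlap", 0.6)),
        min_separation_um=float(params.get("min_separation_um", 1.2)),
    )
    img, truth = phantoms.generate_vesicle_field(vp, imaging)
    dets = detect_vesicles(
        img,
        min_diameter_um=max(vp.diameter_um_mean - 4 * vp.diameter_um_sd, 0.15),
        max_diameter_um=vp.diameter_um_mean + 6 * vp.diameter_um_sd,
    )
    pf = float(params.get("presence_factor", 2.0))
    for d in dets:
        classify_cargo(d, img, "ch1", "ch2", presence_factor=pf)
    counted = census(dets)
    planted = {"both": 0, "ch1_only": 0, "ch2_only": 0}
    for v in truth.vesicles:
        planted[v["cargo_class"]] += 1
    n_planted = len(truth.vesicles)
    return {
        "n_planted": n_planted,
        "n_detected": counted.n_total,
        "detected_counts": {
            "both": counted.n_both,
            "ch1_only": counted.n_ch1_only,
            "ch2_only": counted.n_ch2_only,
        },
        "detected_proportions": counted.proportions,
        "planted_counts": planted,
        "planted_proportions": {
            k: v / n_planted if n_planted else float("nan") for k, v in planted.items()
        },
    }


def run_coloc_overlap(params: dict, config: PipelineConfig, seed: int) -> dict:
    """Dual-cargo endosome field -> per-object colocalized-signal fraction."""
    imaging = _imaging(config, params, seed)
    vp = VesicleFieldParams(
        n_vesicles=int(params.get("n_vesicles", 118)),
        p_both=1.0,
        p_ch1_only=0.0,
        p_ch2_only=0.0,
        within_vesicle_overlap=float(params.get("within_vesicle_overlap", 0.6)),
        diameter_um_mean=float(params.get("diameter_um_mean", 0.6)),
        diameter_um_sd=float(params.get("diameter_um_sd", 0.05)),
        min_separation_um=float(params.get("min_separation_um", 1.2)),
    )
    img, truth = phantoms.generate_vesicle_field(vp, imaging)
    cp = ColocParams(ratio_cutoff=float(params.get("ratio_cutoff", 0.5)))
    objects = [
        (v["centroid"], (v["diameter_um"] / 2) / imaging.pixel_size_um + 2.0)
        for v in truth.vesicles
    ]
    res = per_object_coloc(img, "ch1", "ch2", objects, cp)
    mean_frac = res.mean_object_fraction  # type: ignore[attr-defined]
    return {
        "n_objects": len(objects),
        "n_excluded": sum(o["excluded"] for o in res.per_object),
        "mean_object_fraction": mean_frac,
        "field_fraction_ch1": res.fraction_ch1,
        "field_fraction_ch2": res.fraction_ch2,
        "planted_overlap": vp.within_vesicle_overlap,
    }


def run_diameter_recovery(params: dict, config: PipelineConfig, seed: int) -> dict:
    """Single-cargo vesicle field -> detection -> mean measured diameter."""
    imaging = _imaging(config, params, seed)
    d_um = float(params["diameter_um"])
    vp = VesicleFieldParams(
        n_vesicles=int(params.get("n_vesicles", 30)),
        p_both=0.0,
        p_ch1_only=1.0,
        p_ch2_only=0.0,
        diameter_um_mean=d_um,
        diameter_um_sd=float(params.get("diameter_um_sd", 0.0)),
        min_separation_um=float(params.get("min_separation_um", max(3 * d_um, 1.0))),
    )
    img, truth = phantoms.generate_vesicle_field(vp, imaging)
    dets = detect_vesicles(
        img,
        channels=["ch1"],
        min_diameter_um=d_um * 0.3,
        max_diameter_um=d_um * 3.0,
        psf_sigma_um=imaging.psf_sigma_um,
    )
    measured = [d.diameter_um for d in dets]
    return {
        "n_planted": len(truth.vesicles),
        "n_detected": len(measured),
        "planted_diameter_um": d_um,
        "mean_measured_diameter_um": float(np.mean(measured)) if measured else float("nan"),
        "sd_measured_diameter_um": float(np.std(measured, ddof=1)) if len(measured) > 1 else float("nan"),
    }


def run_nuclei_count(params: dict, config: PipelineConfig, seed: int) -> dict:
    """Nuclei phantoms -> blob/watershed counting -> exact-recovery rate."""
    n_images = int(params.get("n_images", 4))
    n_nuclei = params.get("n_nuclei", 25)
    seeds = _stage_seeds(seed, n_images)
    planted, counted = [], []
    for i in range(n_images):
        n = int(n_nuclei[i] if isinstance(n_nuclei, list) else n_nuclei)
        imaging = _imaging(config, params, seeds[i])
        np_params = NucleiFieldParams(
            n_nuclei=n,
            nucleus_diameter_um=float(params.get("nucleus_diameter_um", 2.5)),
        )
        img, truth = phantoms.generate_nuclei_field(np_params, imaging)
        planted.append(len(truth.nuclei))
        counted.append(count_nuclei(img, "nuclei"))
    return {
        "planted_counts": planted,
        "measured_counts": counted,
        "mean_planted": float(np.mean(planted)),
        "mean_measured": float(np.mean(counted)),
        "exact_fraction": float(np.mean(np.array(planted) == np.array(counted))),
    }


def run_junction_comparison(params: dict, config: PipelineConfig, seed: int) -> dict:
    """Junction lattices per group -> angle classification -> length report."""
    groups: dict = params["groups"]
    seeds = iter(_stage_seeds(seed, len(groups)))
    segments = []
    for gname in sorted(groups):
        g = groups[gname]
        imaging = _imaging(config, params, next(seeds))
        jp = JunctionLatticeParams(
            n_cells=int(params.get("n_cells", 50)),
            axial_length_um=float(g["axial_length_um"]),
            circumferential_length_um=float(g["circumferential_length_um"]),
            length_sd_um=float(params.get("length_sd_um", 0.15)),
            orientation_jitter_deg=float(params.get("orientation_jitter_deg", 5.0)),
        )
        _, truth = phantoms.generate_junction_lattice(jp, imaging)
        for s in truth.junction_segments:
            segments.append(
                make_segment(
                    PolylineROI(s["polyline"]),
                    imaging.pixel_size_um,
                    group=gname,
                )
            )
    summary, comparisons = summarize_junctions(segments)
    return {
        "summary": summary.to_dict(orient="records"),
        "comparisons": {
            k: {
                "t": c.t_statistic,
                "p": c.p_value,
                "star": c.star,
                "means": list(c.means),
                "n": list(c.n),
            }
            for k, c in comparisons.items()
        },
    }


_RUNNERS = {
    "straight_ratio": None,  # handled inline (needs imaging only)
    "tube_cohorts": run_tube_cohorts,
    "vesicle_census": run_vesicle_census,
    "coloc_overlap": run_coloc_overlap,
    "diameter_recovery": run_diameter_recovery,
    "nuclei_count": run_nuclei_count,
    "junction_comparison": run_junction_comparison,
}


def run_experiment(
    config: PipelineConfig | dict | str | Path,
    out_dir: str | Path | None = None,
    seed: int | None = None,
) -> dict:
    """Execute a pipeline config and return (and optionally write) results.

    ``seed`` overrides the config's seed.  Stage failures abort with the
    stage name and cause; results for earlier stages are retained in the
    output directory.
    """
    if isinstance(config, (str, Path)):
        config = PipelineConfig.from_yaml(config)
    elif isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    base_seed = config.seed if seed is None else int(seed)
    stage_seeds = _stage_seeds(base_seed, len(config.stages))

    out_path = Path(out_dir or config.output_dir) if (out_dir or config.output_dir) else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
        (out_path / "config.yaml").write_text(yaml.safe_dump(config.to_dict()))

    results: dict = {"name": config.name, "seed": base_seed, "stages": []}
    for i, st in enumerate(config.stages):
        kind = st["kind"]
        params = st.get("params", {}) or {}
        try:
            if kind == "straight_ratio":
                res = run_straight_ratio(params, _imaging(config, params, stage_seeds[i]))
            else:
                res = _RUNNERS[kind](params, config, stage_seeds[i])
        except Exception as exc:
            if out_path is not None:
                (out_path / "results.partial.json").write_text(
                    json.dumps(results, indent=1, default=float)
                )
            raise type(exc)(f"stage {i} ({kind}) failed: {exc}") from exc
        results["stages"].append({"kind": kind, "result": res})

    if out_path is not None:
        cfg_text = yaml.safe_dump(config.to_dict())
        from . import __version__

        results["provenance"] = {
            "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
            "seed": base_seed,
            "package_version": __version__,
        }
        (out_path / "results.json").write_text(
            json.dumps(results, indent=1, default=float)
        )
    return results


# --------------------------------------------------------------------------
# bundled recipes


def bundled_recipes() -> list[str]:
    """Names of the recipe YAMLs shipped with the package."""
    root = resources.files("tracheoquant") / "recipes"
    return sorted(p.name for p in root.iterdir() if p.name.endswith(".yaml"))


def load_recipe(name: str) -> PipelineConfig:
    """Load and validate a bundled recipe by file name (with or without
    the .yaml extension)."""
    if not name.endswith(".yaml"):
        name += ".yaml"
    root = resources.files("tracheoquant") / "recipes"
    path = root / name
    try:
        text = path.read_text()
    except FileNotFoundError:
        raise ConfigError(
            f"no bundled recipe {name!r}; available: {bundled_recipes()}"
        ) from None
    return PipelineConfig.from_dict(yaml.safe_load(text))
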