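"""End-to-end orchestration: simulate -> preprocess -> assign -> power -> test -> stats -> maps.

A run is driven by one YAML config and one master seed.  Every random
draw flows from that seed through named substreams (per-subject
generation, per-test permutations), so re-running with the same config
reproduces every output table bit-identically.  Stage outputs are plain
TSV/JSON so any stage can be inspected or replaced.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data_model import (
    BandDefinition,
    DEFAULT_BANDS,
    ElectrodeTable,
    ValidationError,
    write_electrodes,
    write_events,
    write_label_volume,
    write_recording,
)
from .condition_power import (
    ExclusionRule,
    condition_power_table,
    segment_trials,
)
from .group_stats import (
    ap_shift_test,
    distance_separation_test,
    network_lme_table,
    proportion_table,
)
from .network_assignment import assign_network, project_hemisphere
from .preprocess import bandpass_bank, bipolar_rereference, downsample, instantaneous_power, notch_filter
from .rotation_test import build_loop, permutation_test
from .spatial_maps import lattice_points, smooth_to_points
from .synthetic_data import EffectSpec, SessionPlan, make_parcellation, make_session, make_strips

log = logging.getLogger("gammamap")

__all__ = ["default_config", "load_config", "validate_config", "run_pipeline", "run_subject"]


def default_config() -> dict:
    """Reference configuration for a desk-scale synthetic run."""
    return {
        "seed": 0,
        "n_subjects": 3,
        "fs": 2000.0,
        "analysis_fs": 2000.0,
        "n_perm": 500,
        "alpha": 0.05,
        "bands": {b.name: [b.lo_hz, b.hi_hz] for b in DEFAULT_BANDS},
        "contrasts": [["switch", "count"], ["count", "rest"]],
        "exclusion": {"rest_edge_s": 2.0, "task_edge_s": 1.0, "switch_extra_start_s": 3.0},
        "notch": {"bases": [50.0, 79.0], "bandwidth_hz": 1.0},
        "assign": {"radius_mm": 5.0},
        "maps": {"radius_mm": 10.0, "spacing_mm": 4.0, "band": "HG", "contrast": "switch_vs_count"},
        "simulate": {
            "n_strips": 3,
            "contacts_per_strip": 4,
            "pitch_mm": 10.0,
            "parcellation": {
                "shape": [40, 40, 40],
                "voxel_mm": 4.0,
                "origin_mm": [-80.0, -80.0, -80.0],
                "blobs": [
                    ["FPN", [0.0, 30.0, 30.0], 30.0],
                    ["DMN", [0.0, -40.0, 30.0], 25.0],
                    ["MOT", [-40.0, 0.0, 40.0], 20.0],
                ],
            },
            "effects": {"modulation": {"FPN:HG:switch": 1.5}},
            "plan": {},
        },
    }


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    merged = default_config()
    _deep_update(merged, cfg or {})
    return merged


def _deep_update(base: dict, extra: dict) -> None:
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v


def _bands_from_config(cfg: dict) -> list[BandDefinition]:
    return [BandDefinition(name, float(lo), float(hi)) for name, (lo, hi) in cfg["bands"].items()]


def validate_config(cfg: dict) -> None:
    """Pre-flight schema and consistency checks; raises before any
    computation on violation."""
    required = ("seed", "n_subjects", "fs", "analysis_fs", "n_perm", "bands", "contrasts")
    for key in required:
        if key not in cfg:
            raise ValidationError(f"config missing required key {key!r}")
    nyq = float(cfg["analysis_fs"]) / 2.0
    for band in _bands_from_config(cfg):
        if band.hi_hz >= nyq:
            raise ValidationError(
                f"band {band.name} upper edge {band.hi_hz} Hz is not below the analysis "
                f"Nyquist {nyq} Hz"
            )
    for pair in cfg["contrasts"]:
        if len(pair) != 2:
            raise ValidationError(f"contrast must be a pair, got {pair}")
    if int(cfg["n_perm"]) < 100:
        raise ValidationError("n_perm below the practical floor of 100")


def _effects_from_config(cfg: dict) -> EffectSpec:
    sim = cfg["simulate"].get("effects", {})
    modulation = {}
    for key, gain in sim.get("modulation", {}).items():
        net, band, cond = key.split(":")
        modulation[(net, band, cond)] = float(gain)
    kwargs = {k: v for k, v in sim.items() if k != "modulation"}
    return EffectSpec(modulation=modulation, **kwargs)


def _parcellation_from_config(cfg: dict):
    par = cfg["simulate"]["parcellation"]
    vox = float(par["voxel_mm"])
    affine = np.diag([vox, vox, vox, 1.0])
    affine[:3, 3] = par.get("origin_mm", [0.0, 0.0, 0.0])
    blobs = [(name, tuple(centre), float(radius)) for name, centre, radius in par["blobs"]]
    return make_parcellation(tuple(par["shape"]), affine, blobs)


def run_subject(cfg: dict, subject_seed: int, subject_id: str,
                out_dir: Path | None = None) -> dict[str, Any]:
    """Simulate and analyze one subject; returns in-memory tables.

    The per-subject seed drives strip placement, the session generator
    and the permutation streams for that subject.
    """
    rng = np.random.default_rng(subject_seed)
    sim = cfg["simulate"]
    labels = _parcellation_from_config(cfg)
    effects = _effects_from_config(cfg)
    plan = SessionPlan(**sim.get("plan", {}))
    bands = _bands_from_config(cfg)
    rule = ExclusionRule(**cfg["exclusion"])

    # optional fixed placement, e.g. one strip centred per network blob so
    # every strip carries an unambiguous network; random otherwise
    placement = sim.get("placement")
    strips = make_strips(
        sim["n_strips"], sim.get("contacts_per_strip", 4), sim.get("pitch_mm", 10.0),
        placement=placement, seed=int(rng.integers(2**31)),
    )
    rec, events, truth = make_session(
        plan, effects, strips, labels, fs=float(cfg["fs"]), seed=int(rng.integers(2**31)),
        bands=tuple(bands),
    )

    if out_dir is not None:
        write_recording(out_dir / f"{subject_id}_raw.f32", rec)
        write_events(out_dir / f"{subject_id}_events.tsv", events)
        write_electrodes(out_dir / f"{subject_id}_electrodes.tsv", strips)
        (out_dir / f"{subject_id}_ground_truth.json").write_text(json.dumps(truth, indent=1))

    # preprocess
    rec = downsample(rec, float(cfg["analysis_fs"]))
    strips_assigned = assign_network(strips, labels, radius_mm=float(cfg["assign"]["radius_mm"]))
    rec, derived = bipolar_rereference(rec, strips_assigned)
    rec = notch_filter(rec, base_freqs=cfg["notch"]["bases"],
                       bandwidth_hz=float(cfg["notch"]["bandwidth_hz"]))

    band_recs = bandpass_bank(rec, bands)
    band_powers = [instantaneous_power(br, band) for br, band in zip(band_recs, bands)]

    contrasts = tuple((c1, c2) for c1, c2 in cfg["contrasts"])
    cp = condition_power_table(band_powers, events, rule, contrasts)

    perm_rows = []
    perm_seed_rng = np.random.default_rng(int(rng.integers(2**31)))
    for bp in band_powers:
        segments = segment_trials(bp, events, rule)
        for pair in contrasts:
            for ch, name in enumerate(bp.channel_names):
                loop, markers = build_loop(bp.power[ch], segments, pair)
                res = permutation_test(
                    loop, markers, pair, n_perm=int(cfg["n_perm"]),
                    rng=int(perm_seed_rng.integers(2**31)), alpha=float(cfg["alpha"]),
                )
                perm_rows.append({
                    "subject": subject_id, "electrode": name, "band": bp.band.name,
                    "contrast": f"{pair[0]}_vs_{pair[1]}",
                    "observed_ratio": res.observed_ratio, "p": res.p_two_tailed,
                    "q_low": res.q_low, "q_high": res.q_high,
                    "significant": res.significant, "direction": res.direction,
                })
    results = pd.DataFrame(perm_rows)
    cp.means.insert(0, "subject", subject_id)
    cp.contrasts.insert(0, "subject", subject_id)
    derived_df = derived.contacts.copy()
    derived_df.insert(0, "subject", subject_id)
    # electrode names are unique only within a subject; prefix for pooling
    for frame in (cp.means, cp.contrasts, results):
        frame["electrode"] = subject_id + ":" + frame["electrode"]
    derived_df["name"] = subject_id + ":" + derived_df["name"]
    return {
        "means": cp.means, "contrasts": cp.contrasts, "results": results,
        "derived": derived_df, "ground_truth": truth,
    }


def run_pipeline(config: str | Path | dict, out_dir: str | Path | None = None) -> Path:
    """Run the full synthetic pipeline and write all stage outputs.

    Returns the run directory.  Re-running with the same config and seed
    reproduces every table bit-identically.
    """
    cfg = load_config(config) if not isinstance(config, dict) else _merged(config)
    validate_config(cfg)
    out = Path(out_dir if out_dir is not None else cfg.get("out_dir", "gammamap_run"))
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    master = np.random.default_rng(int(cfg["seed"]))
    subject_seeds = master.integers(0, 2**31, size=int(cfg["n_subjects"]))

    labels = _parcellation_from_config(cfg)
    write_label_volume(out / "parcellation.nii.gz", labels, labels_tsv=out / "labels.tsv")

    pooled: dict[str, list[pd.DataFrame]] = {"means": [], "contrasts": [], "results": [], "derived": []}
    for i, sseed in enumerate(subject_seeds):
        sid = f"sub-{i + 1:02d}"
        log.info("subject %s (seed %d)", sid, sseed)
        st = time.time()
        tables = run_subject(cfg, int(sseed), sid, out_dir=out)
        for key in pooled:
            pooled[key].append(tables[key])
        log.info("subject %s done in %.1fs", sid, time.time() - st)

    means = pd.concat(pooled["means"], ignore_index=True)
    contrasts = pd.concat(pooled["contrasts"], ignore_index=True)
    results = pd.concat(pooled["results"], ignore_index=True)
    derived = pd.concat(pooled["derived"], ignore_index=True)
    derived_table = ElectrodeTable(
        derived.drop(columns=["subject"]).assign(
            strip_id=derived["subject"] + ":" + derived["strip_id"].astype(str))
    )

    means.to_csv(out / "condition_power.tsv", sep="\t", index=False)
    contrasts.to_csv(out / "percent_change.tsv", sep="\t", index=False)
    results.to_csv(out / "permutation_results.tsv", sep="\t", index=False)
    write_electrodes(out / "electrodes_derived.tsv", derived_table)

    # group statistics
    prop = pd.concat([
        proportion_table(results, derived_table, grouping="fpn_vs_rest"),
        proportion_table(results, derived_table, grouping="network"),
    ], ignore_index=True)
    prop.to_csv(out / "proportions.tsv", sep="\t", index=False)

    lme_input = contrasts.merge(results[["electrode", "band", "contrast"]].drop_duplicates(),
                                on=["electrode", "band", "contrast"])
    lme = pd.concat([
        network_lme_table(lme_input, derived_table, per_network=False),
        network_lme_table(lme_input, derived_table, per_network=True),
    ], ignore_index=True)
    lme.to_csv(out / "lme_contrasts.tsv", sep="\t", index=False)

    focality_bands = [b for b in ("HG", "LG", "beta") if b in set(results["band"])]
    main_contrast = f"{cfg['contrasts'][0][0]}_vs_{cfg['contrasts'][0][1]}"
    sig_coords = {}
    coords_by_name = dict(zip(derived_table.contacts["name"],
                              map(tuple, derived_table.coords)))
    for band in focality_bands:
        sel = results[(results["band"] == band) & (results["contrast"] == main_contrast)
                      & results["significant"]]
        sig_coords[band] = np.array([coords_by_name[e] for e in sel["electrode"]], dtype=float).reshape(-1, 3)
    dist_tests = distance_separation_test(sig_coords)
    dist_tests.to_csv(out / "distance_tests.tsv", sep="\t", index=False)

    ap_rows = []
    if len(cfg["contrasts"]) >= 2 and "HG" in set(results["band"]):
        c_a = main_contrast
        c_b = f"{cfg['contrasts'][1][0]}_vs_{cfg['contrasts'][1][1]}"
        for band in ("HG", "LG"):
            ya = _sig_y(results, coords_by_name, band, c_a, "increase")
            yb = _sig_y(results, coords_by_name, band, c_b, "increase")
            stat, p, direction = ap_shift_test(ya, yb)
            ap_rows.append({"band": band, "contrast_a": c_a, "contrast_b": c_b,
                            "n_a": ya.size, "n_b": yb.size,
                            "statistic": stat, "p": p, "direction": direction})
    pd.DataFrame(ap_rows).to_csv(out / "ap_shift.tsv", sep="\t", index=False)

    # smoothed display map for the configured band/contrast
    mc = cfg["maps"]
    disp = project_hemisphere(derived_table)
    vals = contrasts[(contrasts["band"] == mc["band"]) & (contrasts["contrast"] == mc["contrast"])]
    vals = vals.set_index("electrode")["percent_change"]
    elec_vals = vals.reindex(disp.contacts["name"]).to_numpy()
    ok = np.isfinite(elec_vals)
    points = lattice_points(disp.coords[ok], spacing_mm=float(mc["spacing_mm"]))
    smooth = smooth_to_points(elec_vals[ok], disp.coords[ok], points,
                              radius_mm=float(mc["radius_mm"]))
    smooth.to_csv(out / "map_points.tsv", sep="\t", index=False)

    manifest = {
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest(),
        "seed": int(cfg["seed"]),
        "versions": _versions(),
        "elapsed_s": round(time.time() - t0, 2),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return out


def _sig_y(results: pd.DataFrame, coords_by_name: dict, band: str, contrast: str,
           direction: str) -> np.ndarray:
    sel = results[(results["band"] == band) & (results["contrast"] == contrast)
                  & results["significant"] & (results["direction"] == direction)]
    return np.array([coords_by_name[e][1] for e in sel["electrode"]], dtype=float)


def _merged(cfg: dict) -> dict:
    merged = default_config()
    _deep_update(merged, cfg)
    return merged


def _versions() -> dict:
    import scipy
    import statsmodels

    return {
        "gammamap": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "statsmodels": statsmodels.__version__,
    }
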