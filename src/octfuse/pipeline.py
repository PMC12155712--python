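"""End-to-end pipeline orchestration from a single validated configuration.

Stages (each can be toggled): simulate -> blinks -> motion -> illum ->
fuse -> enface -> track.  The configuration is a strict schema (unknown
keys are rejected with the offending key named); one global seed drives
every random element, so reruns with identical config and seed are
bit-reproducible.  The run manifest lists every written artifact with its
content hash, per-stage wall times and the effective configuration.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Literal

import numpy as np
from pydantic import BaseModel, ConfigDict, ValidationError

from . import enface, fuse, illum, ingest, motion, simkit, track
from .protocol import AcquisitionProtocol

ALL_STAGES = ("simulate", "blinks", "motion", "illum", "fuse", "enface",
              "track")


class ConfigError(ValueError):
    pass


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ProtocolCfg(_Strict):
    fov_mm: float = 6.0
    ascans_per_bscan: int = 500
    bscans_per_volume: int = 500
    ascan_rate_hz: float = 128_000.0
    volume_duration_s: float = 2.4
    inter_volume_gap_s: float = 0.04
    n_volumes: int = 6

    def build(self) -> AcquisitionProtocol:
        return AcquisitionProtocol(**self.model_dump())


class PhantomCfg(_Strict):
    nz: int = 256
    axial_um: float = 2.0
    undulation_amp_um: float = 30.0
    undulation_corr_um: float = 600.0
    n_sdds: int = 80              # ~2.3 per mm^2 over a 6 x 6 mm field
    n_drusen: int = 2
    druse_radius_um: float = 150.0
    druse_height_um: float = 40.0


class MotionSimCfg(_Strict):
    drift_sd_um: float = 10.0
    axial_sd_um: float = 5.0
    saccade_rate_hz: float = 0.25
    saccade_mean_um: float = 60.0
    saccade_sd_um: float = 20.0


class NoiseCfg(_Strict):
    speckle_contrast: float = 0.25
    detector_noise_sd: float = 0.005
    bias_amp: float = 0.2         # +-20% smooth illumination bias
    bias_corr_frac: float = 0.25  # bias correlation length / field size


class BlinkCfg(_Strict):
    n_blinks: int = 1
    blink_bscans: int = 10
    rel_threshold: float = ingest.DEFAULT_BLINK_THRESHOLD


class SlabCfg(_Strict):
    reference: Literal["BrM", "pRPE"] = "BrM"
    lower_um: float = 27.0
    upper_um: float = 77.0

    def build(self) -> enface.SlabSpec:
        return enface.SlabSpec(self.reference, self.lower_um, self.upper_um)


class TrackCfg(_Strict):
    match_radius_um: float = 60.0
    laterality: Literal["OD", "OS"] = "OD"
    fovea_um: tuple[float, float] | None = None   # None = field centre


class FollowupCfg(_Strict):
    enabled: bool = True
    n_stable: int = 10
    n_regress: int = 2
    n_fuse_pairs: int = 1
    n_new: int = 1
    shift_um: tuple[float, float] = (30.0, -20.0)


class PipelineConfig(_Strict):
    seed: int = 0
    stages: list[Literal["simulate", "blinks", "motion", "illum", "fuse",
                         "enface", "track"]] = list(ALL_STAGES)
    out_dir: str = "octfuse_run"
    protocol: ProtocolCfg = ProtocolCfg()
    phantom: PhantomCfg = PhantomCfg()
    motion_sim: MotionSimCfg = MotionSimCfg()
    noise: NoiseCfg = NoiseCfg()
    blinks: BlinkCfg = BlinkCfg()
    slab: SlabCfg = SlabCfg()
    track: TrackCfg = TrackCfg()
    followup: FollowupCfg = FollowupCfg()
    target_row_frac: float = 0.75

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        raw = yaml.safe_load(Path(path).read_text()) or {}
        try:
            return cls(**raw)
        except ValidationError as e:
            first = e.errors()[0]
            key = ".".join(str(p) for p in first["loc"])
            raise ConfigError(
                f"invalid configuration key {key!r}: {first['msg']}") from e


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def process_visit(cfg: PipelineConfig, sdds: list[simkit.SDD],
                  seed: int, visit: str, out: Path,
                  shift_um: tuple[float, float] = (0.0, 0.0),
                  manifest: dict | None = None,
                  scene_seed: int | None = None,
                  drusen: list[simkit.Druse] | None = None) -> dict:
    """Simulate and process one visit through to its en face slab.

    Returns a dict with the slab, fused volume, phantom ground truth and
    per-stage timings.  ``shift_um`` moves the scanned field relative to
    the retina (inter-visit fixation offset); the retina itself — drusen
    and surface shape — is drawn from ``scene_seed`` so it persists across
    visits while acquisition noise and eye motion follow ``seed``."""
    rng = np.random.default_rng(seed)
    proto = cfg.protocol.build()
    ext = proto.fov_mm * 1000.0
    stages = cfg.stages
    res: dict = {"visit": visit, "timings": {}}
    if scene_seed is None:
        scene_seed = seed

    def tick(name, t0):
        res["timings"][name] = round(time.perf_counter() - t0, 3)

    # ---- simulate --------------------------------------------------------
    t0 = time.perf_counter()
    if drusen is None:
        drusen = place_drusen(cfg, sdds, scene_seed)
    drusen = [simkit.Druse(d.x_um - shift_um[0], d.y_um - shift_um[1],
                           d.radius_um, d.height_um) for d in drusen]
    shifted = [simkit.SDD(s.x_um - shift_um[0], s.y_um - shift_um[1],
                          s.radius_um, s.stage) for s in sdds]
    pcfg = simkit.PhantomConfig(
        nx=proto.ascans_per_bscan, ny=proto.bscans_per_volume,
        nz=cfg.phantom.nz, pitch_um=proto.pitch_um,
        axial_um=cfg.phantom.axial_um,
        undulation_amp_um=cfg.phantom.undulation_amp_um,
        undulation_corr_um=cfg.phantom.undulation_corr_um,
        drusen=tuple(drusen), sdds=tuple(shifted), seed=scene_seed + 1)
    phantom = simkit.make_phantom(pcfg)
    mp = cfg.motion_sim
    traces = [simkit.simulate_motion(
        proto.volume_duration_s + 0.05,
        simkit.MotionParams(mp.drift_sd_um, mp.axial_sd_um,
                            mp.saccade_rate_hz, mp.saccade_mean_um,
                            mp.saccade_sd_um, seed=seed + 100 + v),
        t0=proto.volume_start_s(v) - 0.02) for v in range(proto.n_volumes)]
    bias = None
    if cfg.noise.bias_amp > 0:
        nb, nf = proto.bscans_per_volume, proto.ascans_per_bscan
        bias = [np.exp(simkit.smooth_random_field(
            (nb, nf), cfg.noise.bias_corr_frac * nf,
            np.log1p(cfg.noise.bias_amp),
            np.random.default_rng(seed + 200 + v))).astype(np.float32)
            for v in range(proto.n_volumes)]
    volumes = simkit.acquire(phantom, proto, traces, bias=bias,
                             speckle_contrast=cfg.noise.speckle_contrast,
                             detector_noise_sd=cfg.noise.detector_noise_sd,
                             seed=seed + 2)
    if "blinks" in stages and cfg.blinks.n_blinks > 0:
        nb = proto.bscans_per_volume
        for v in range(min(cfg.blinks.n_blinks, len(volumes))):
            b0 = int(rng.integers(nb // 4, 3 * nb // 4))
            volumes[v] = simkit.inject_blinks(
                volumes[v], [(b0, min(nb, b0 + cfg.blinks.blink_bscans))])
    res["phantom"] = phantom
    res["traces"] = traces
    res["volumes"] = volumes
    tick("simulate", t0)

    # ---- blinks ----------------------------------------------------------
    if "blinks" in stages:
        t0 = time.perf_counter()
        res["blink_indices"] = {
            v.volume_index: ingest.detect_blinks(v, cfg.blinks.rel_threshold)
            for v in volumes}
        tick("blinks", t0)

    # ---- motion ----------------------------------------------------------
    t0 = time.perf_counter()
    if "motion" in stages:
        model = motion.estimate_motion(volumes)
    else:
        model = motion.DisplacementModel.zero(volumes)
    res["model"] = model
    tick("motion", t0)

    if not ({"fuse", "enface"} & set(stages)):
        return res

    samples = [motion.correct(v, model) for v in volumes]

    # ---- illum -----------------------------------------------------------
    if "illum" in stages:
        t0 = time.perf_counter()
        gain = illum.estimate_gain(samples)
        gain.scale = illum.match_brightness(samples)
        samples = [illum.apply_gain(s, gain) for s in samples]
        res["gain"] = gain
        tick("illum", t0)

    # ---- fuse ------------------------------------------------------------
    t0 = time.perf_counter()
    shape2 = (proto.bscans_per_volume, proto.ascans_per_bscan)
    brm = fuse.mean_surface(
        [fuse.segment_surface(v, fuse.BRM) for v in volumes], model, shape2)
    prpe = fuse.mean_surface(
        [fuse.segment_surface(v, fuse.PRPE) for v in volumes], model, shape2)
    target_row = int(round(cfg.target_row_frac * cfg.phantom.nz))
    fused = fuse.flatten_and_merge(samples, brm, target_row)
    fused.surfaces[fuse.PRPE] = fused.surfaces[fuse.BRM] - \
        (brm.filled() - prpe.filled())
    res["fused"] = fused
    res["surfaces"] = {"BrM": brm, "pRPE": prpe}
    tick("fuse", t0)

    # ---- enface ----------------------------------------------------------
    if "enface" not in stages:
        return res
    t0 = time.perf_counter()
    slab = enface.make_slab(fused, cfg.slab.build(), visit=visit)
    res["slab"] = slab
    res["slab_prpe"] = enface.make_slab(
        fused, enface.SlabSpec(fuse.PRPE, cfg.slab.lower_um,
                               cfg.slab.upper_um), visit=visit)
    tick("enface", t0)

    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        fused.save(out / f"fused_{visit}")
        slab.save(out / f"slab_{visit}")
        model.save(out / f"motion_{visit}.json")
        if manifest is not None:
            for p in sorted(out.glob(f"*_{visit}*")):
                manifest["artifacts"][str(p)] = _sha256(p)
    return res


def place_drusen(cfg: PipelineConfig, avoid_sdds: list[simkit.SDD],
                 scene_seed: int) -> list[simkit.Druse]:
    """Drusen positions in the retina frame, kept clear of the deposits so
    the two pathologies stay individually resolvable."""
    ext = cfg.protocol.fov_mm * 1000.0
    drng = np.random.default_rng(scene_seed + 17)
    out: list[simkit.Druse] = []
    clearance = cfg.phantom.druse_radius_um + 80.0
    for _ in range(cfg.phantom.n_drusen):
        for _try in range(200):
            x = float(drng.uniform(0.15 * ext, 0.85 * ext))
            y = float(drng.uniform(0.15 * ext, 0.85 * ext))
            if all((x - s.x_um) ** 2 + (y - s.y_um) ** 2 >
                   (clearance + s.radius_um) ** 2 for s in avoid_sdds):
                out.append(simkit.Druse(x, y, cfg.phantom.druse_radius_um,
                                        cfg.phantom.druse_height_um))
                break
    return out


def druse_filtered(dets: list[track.SDDetection],
                   slab_prpe, min_rel: float = 0.1
                   ) -> list[track.SDDetection]:
    """Drop detections that vanish in the pRPE-referenced slab.

    Subretinal deposits sit anterior to the RPE and stay visible above the
    posterior RPE boundary, whereas soft drusen (sub-RPE material) do not —
    so confirming each candidate against the pRPE slab separates dot SDDs
    from drusen without any ground-truth knowledge."""
    if slab_prpe is None or not dets:
        return dets
    import numpy as _np
    from scipy import ndimage as _ndi
    pitch = slab_prpe.pitch_um
    img = slab_prpe.filled(float(_np.nanmedian(slab_prpe.image)))
    high = img - _ndi.gaussian_filter(img, 300.0 / pitch)
    scale = float(_np.quantile(_np.abs(high), 0.999)) or 1.0
    keep = []
    for d in dets:
        iy = int(round(d.y_um / pitch))
        ix = int(round(d.x_um / pitch))
        iy = min(max(iy, 0), img.shape[0] - 1)
        ix = min(max(ix, 0), img.shape[1] - 1)
        if high[iy, ix] / scale > min_rel:
            keep.append(d)
    return keep


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages; returns the run manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": cfg.model_dump(), "artifacts": {},
                      "timings": {}, "stages": list(cfg.stages)}
    t_start = time.perf_counter()

    ext = cfg.protocol.fov_mm * 1000.0
    fu = cfg.followup
    if fu.enabled and "track" in cfg.stages:
        base_sdds, fol_sdds, expected = simkit.longitudinal_sdd_pair(
            ext, fu.n_stable, fu.n_regress, fu.n_fuse_pairs, fu.n_new,
            seed=cfg.seed + 7)
        manifest["expected_changes"] = expected
    else:
        rng = np.random.default_rng(cfg.seed + 7)
        base_sdds = simkit.random_sdds(cfg.phantom.n_sdds, ext, rng)
        fol_sdds = None

    all_sdds = base_sdds + (fol_sdds or [])
    drusen = place_drusen(cfg, all_sdds, cfg.seed)
    try:
        base = process_visit(cfg, base_sdds, cfg.seed, "baseline", out,
                             manifest=manifest, scene_seed=cfg.seed,
                             drusen=drusen)
        manifest["timings"]["baseline"] = base["timings"]

        if fol_sdds is not None:
            fol = process_visit(cfg, fol_sdds, cfg.seed + 1000, "followup",
                                out, shift_um=fu.shift_um, manifest=manifest,
                                scene_seed=cfg.seed, drusen=drusen)
            manifest["timings"]["followup"] = fol["timings"]

            t0 = time.perf_counter()
            tf = track.register_visits(base["slab"], fol["slab"])
            dets_b = druse_filtered(
                track.detect_sdd(base["slab"], visit="baseline"),
                base.get("slab_prpe"))
            dets_f = druse_filtered(
                track.detect_sdd(fol["slab"], visit="followup"),
                fol.get("slab_prpe"))
            records = track.classify_changes(dets_b, dets_f, tf,
                                             cfg.track.match_radius_um)
            fovea = cfg.track.fovea_um or (ext / 2, ext / 2)
            records = track.records_with_quadrants(
                records, dets_b, dets_f, fovea, cfg.track.laterality)
            table = track.summarize(records)
            manifest["timings"]["track"] = round(
                time.perf_counter() - t0, 3)
            manifest["summary"] = {
                "counts": table.category_counts,
                "percent": table.category_pct,
                "quadrant_counts": table.quadrant_counts,
                "total": table.total}
            table.to_frame().to_csv(out / "summary.csv", index=False)
            (out / "records.csv").write_text(
                "category,baseline_ids,followup_id,quadrant\n" + "\n".join(
                    f"{r.category},{'|'.join(map(str, r.baseline_ids))},"
                    f"{'' if r.followup_id is None else r.followup_id},"
                    f"{r.quadrant}" for r in records))
            for p in ("summary.csv", "records.csv"):
                manifest["artifacts"][str(out / p)] = _sha256(out / p)
    except Exception as e:
        manifest["failed_stage"] = getattr(e, "stage", type(e).__name__)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise

    manifest["timings"]["total"] = round(time.perf_counter() - t_start, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
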