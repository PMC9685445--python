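"""End-to-end pipeline orchestration.

Runs the stages in dependency order on synthetic data with a single master
seed: simulate → calcium → tune → match → project → quality → stats.  The
product is the per-neuron function–projection table (functional indices
joined with per-region axonal length) plus clustering and association
results, and a run manifest with per-output checksums so that determinism
is checkable by re-running.

Every stage draws its randomness from a child of the master seed
(numpy SeedSequence spawning), so stage outputs are pure functions of
(config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    calcium_processing as cal,
    cross_modality_matching as xmod,
    function_projection_stats as fps,
    projection_quantification as proj,
    signal_quality as sq,
    synthetic_data as synth,
    tuning_quantification as tq,
)

__all__ = ["PipelineConfig", "RunManifest", "StageDependencyError", "run_pipeline"]


class StageDependencyError(RuntimeError):
    """An enabled stage is missing its upstream artifact."""


@dataclass
class PipelineConfig:
    """All stage parameters with protocol-standard defaults.

    Defaults follow the study conventions wherever one exists: 10% ΔF/F
    responsiveness threshold repeated ≥ 2 times, 1.0 mm target rule, 40 µm
    SNR sampling interval, k scanned over 2..6 (containing 3).
    """

    out_dir: str = "fawps_run"
    seed: int = 0
    # stage toggles: stats can run standalone on a provided table
    stages: tuple = ("simulate", "calcium", "tune", "match", "project", "quality", "stats")
    table_path: str | None = None
    # simulate
    n_neurons: int = 16
    planted_spearman: float = -0.9
    corr_region: str = "MOs"
    tensor_noise_sd_low: float = 1.5  # ΔF/F %, high-R² classes
    tensor_noise_sd_high: float = 12.0  # ΔF/F %, low-R² class
    node_spacing_um: float = 10.0
    landmark_n: int = 5
    landmark_noise_sd: float = 0.0
    # calcium
    responsive_threshold: float = 10.0
    min_repeats: int = 2
    # tune
    fit_restarts: int = 10
    # match
    match_max_dist: float = 5.0
    # project
    step_um: float = 2.0
    target_threshold_mm: float = 1.0
    # quality
    snr_interval_um: float = 40.0
    # stats
    k_range: tuple = (2, 3, 4, 5, 6)
    kmeans_n_init: int = 50

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("k_range", "stages"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (the output location is not
        part of it)."""
        d = dataclasses.asdict(self)
        d.pop("out_dir")
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    checksums: dict  # filename -> sha256
    stage_log: list = field(default_factory=list)
    elapsed_s: float = 0.0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


REGION_LAYOUT = {
    # region id -> (acronym, box lo/hi in µm, (x, y, z))
    1: ("VISp", (0.0, 0.0, 0.0), (200.0, 300.0, 300.0)),
    2: ("VISa", (200.0, 0.0, 0.0), (400.0, 300.0, 300.0)),
    3: ("VISrl", (400.0, 0.0, 0.0), (600.0, 300.0, 300.0)),
    4: ("MOs", (0.0, 300.0, 0.0), (200.0, 600.0, 300.0)),
    5: ("ACA", (200.0, 300.0, 0.0), (400.0, 600.0, 300.0)),
    6: ("SSp", (400.0, 300.0, 0.0), (600.0, 600.0, 300.0)),
}


def serpentine_waypoints(box_lo, box_hi, length_um: float, margin: float = 15.0) -> np.ndarray:
    """Zig-zag polyline of (approximately exactly) the requested length
    inside an axis-aligned box: back-and-forth passes along x, stepping in
    y, at the box's mid-z plane."""
    lo = np.asarray(box_lo, dtype=float) + margin
    hi = np.asarray(box_hi, dtype=float) - margin
    width = hi[0] - lo[0]
    depth = hi[1] - lo[1]
    z = (lo[2] + hi[2]) / 2.0
    n_passes = max(1, int(np.floor(length_um / width)))
    n_steps = n_passes  # y advance per turn
    dy = min(depth / max(n_steps, 1), 20.0)
    pts = []
    y = lo[1]
    x_left, x_right = lo[0], hi[0]
    pts.append([x_left, y, z])
    remaining = length_um
    at_left = True
    while remaining > 1e-9:
        run = min(remaining, width)
        x_from = x_left if at_left else x_right
        x_to = x_from + run if at_left else x_from - run
        pts.append([x_to, y, z])
        remaining -= run
        if remaining > 1e-9:
            step = min(dy, remaining)
            y = min(y + step, hi[1])
            pts.append([x_to, y, z])
            remaining -= step
        at_left = not at_left
    return np.asarray(pts)


def _simulate_cohort(cfg: PipelineConfig, rng: np.random.Generator) -> dict:
    """Generate the synthetic study: neurons with known tuning, OSI targets,
    and axon geometry planting the configured rank correlation between OSI
    and axonal length in ``corr_region``."""
    from scipy import stats as st

    n = cfg.n_neurons
    # functional classes: (R²-class, OSI-range); low-R² class gets noisy tensors
    classes = rng.permuted(np.arange(n) % 3)
    osi_targets = np.where(
        classes == 0, rng.uniform(0.55, 0.9, n),
        np.where(classes == 1, rng.uniform(0.05, 0.35, n), rng.uniform(0.05, 0.35, n)),
    )
    noise_sds = np.where(classes == 2, cfg.tensor_noise_sd_high, cfg.tensor_noise_sd_low)

    # planted Spearman between OSI and corr_region length (Gaussian copula)
    ranks = st.rankdata(osi_targets)
    z_osi = st.norm.ppf((ranks - 0.5) / n)
    rho_p = 2.0 * np.sin(np.pi * cfg.planted_spearman / 6.0)
    eps = rng.standard_normal(n)
    z_len = rho_p * z_osi + np.sqrt(max(0.0, 1.0 - rho_p**2)) * eps
    corr_lengths_um = 2500.0 * np.exp(0.5 * z_len)  # mm-scale, mostly above target rule

    acronyms = {rid: name for rid, (name, _, _) in REGION_LAYOUT.items()}
    boxes = [(rid, (lo, hi)) for rid, (_, lo, hi) in REGION_LAYOUT.items()]
    volume = synth.gen_label_volume(
        shape_voxels=(30, 60, 60), voxel_um=10.0, region_boxes=boxes, id_to_acronym=acronyms
    )
    corr_rid = next(r for r, (name, _, _) in REGION_LAYOUT.items() if name == cfg.corr_region)
    home_rid = 1  # VISp

    neurons = []
    for i in range(n):
        A = float(rng.uniform(30.0, 80.0))
        sf0 = float(rng.uniform(0.1, 0.8))
        tf0 = float(rng.uniform(0.7, 6.0))
        ssf = float(rng.uniform(0.9, 1.8))
        stf = float(rng.uniform(0.9, 1.8))
        xi = float(rng.uniform(-0.8, 0.8))
        soma = np.array([
            rng.uniform(40.0, 160.0), rng.uniform(40.0, 260.0), rng.uniform(60.0, 240.0)
        ])
        home_len = float(rng.uniform(1500.0, 5000.0))
        branches = [
            (serpentine_waypoints(*REGION_LAYOUT[home_rid][1:], home_len), home_rid),
            (serpentine_waypoints(*REGION_LAYOUT[corr_rid][1:], float(corr_lengths_um[i])), corr_rid),
        ]
        spec = synth.GroundTruthNeuronSpec(
            tuning_params=(A, sf0, tf0, ssf, stf, xi),
            osi_target=float(osi_targets[i]),
            soma_xyz=tuple(soma),
            branch_plan=tuple((b, r) for b, r in branches),
        )
        tensor = synth.gen_response_tensor(
            spec, noise_sd=float(noise_sds[i]), seed=int(rng.integers(2**31))
        )
        swc, analytic = synth.gen_swc_neuron(
            spec, node_spacing=cfg.node_spacing_um, region_boxes=boxes, id_to_acronym=acronyms
        )
        neurons.append(
            {"id": i, "class": int(classes[i]) + 1, "spec": spec, "tensor": tensor,
             "swc": swc, "analytic_mm": analytic}
        )
    true_affine = xmod.AffineTransform2D(
        R=np.array([[np.cos(0.3), np.sin(0.3)], [-np.sin(0.3), np.cos(0.3)]]) * 1.1,
        T=np.array([12.0, -7.0]),
    )
    landmarks = synth.gen_landmark_pair(
        true_affine, n=cfg.landmark_n, noise_sd=cfg.landmark_noise_sd,
        seed=int(rng.integers(2**31)), extent=400.0,
    )
    return {
        "neurons": neurons, "volume": volume, "true_affine": true_affine,
        "landmarks": landmarks, "osi_targets": osi_targets,
    }


def _stats_stage(table: pd.DataFrame, cfg: PipelineConfig, out: Path, seed: int) -> tuple:
    """Clustering + association + group tests on a fawps table; writes the
    stats CSVs and returns (clustering result, association rows)."""
    clus = fps.kmeans_with_ch(
        table[["r2", "osi"]].to_numpy(), k_range=cfg.k_range,
        n_init=cfg.kmeans_n_init, seed=seed,
    )
    pd.DataFrame({"neuron_id": table["neuron_id"], "class": clus.labels}).to_csv(
        out / "clustering.csv", index=False
    )
    skip_cols = {"neuron_id", "r2", "osi", "class_true"}
    regions = [c for c in table.columns if c not in skip_cols]
    assoc_rows = []
    for feature in ("r2", "osi"):
        for region in regions:
            try:
                e = fps.spearman_assoc(
                    table, feature, region, restrict_to_projecting=True,
                    threshold_mm=cfg.target_threshold_mm,
                )
            except ValueError:
                continue
            assoc_rows.append(
                {"feature": e.feature, "region": e.region, "n": e.n,
                 "r": e.r, "p": e.p, "significant": e.significant}
            )
    pd.DataFrame(assoc_rows).to_csv(out / "associations.csv", index=False)
    group_rows = []
    if "class_true" in table.columns:
        by_class = [
            table[table["class_true"] == c]["osi"].to_numpy()
            for c in sorted(table["class_true"].unique())
        ]
        if len(by_class) >= 2 and all(len(g) >= 2 for g in by_class):
            kd = fps.kruskal_dunn(by_class)
            group_rows.append({"test": "kruskal_osi_by_class", "stat": kd["H"], "p": kd["p"]})
    pd.DataFrame(group_rows).to_csv(out / "group_tests.csv", index=False)
    return clus, assoc_rows


def _write_manifest(cfg: PipelineConfig, out: Path, log: list, t_start: float) -> RunManifest:
    checksums = {}
    for f in sorted(out.glob("*.csv")) + sorted(out.glob("summary.json")):
        checksums[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    manifest = RunManifest(
        config_hash=cfg.config_hash(), seed=cfg.seed, checksums=checksums,
        stage_log=log, elapsed_s=time.time() - t_start,
    )
    manifest.to_json(out / "manifest.json")
    return manifest


def run_pipeline(cfg: PipelineConfig) -> RunManifest:
    """Execute the enabled stages in dependency order.

    Writes per-stage CSV artifacts plus ``manifest.json`` into
    ``cfg.out_dir`` and returns the manifest.  ``cfg.stages`` toggles
    stages: the stats stage can run standalone on ``cfg.table_path``; any
    other stage enabled without its upstream raises
    :class:`StageDependencyError` naming the gap.
    """
    t_start = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = []
    seeds = np.random.SeedSequence(cfg.seed).spawn(6)
    rngs = [np.random.default_rng(s) for s in seeds]

    stages = set(cfg.stages)
    upstream = {"calcium", "tune", "match", "project", "quality"}
    if "simulate" not in stages:
        if stages & upstream:
            missing = sorted(stages & upstream)
            raise StageDependencyError(
                f"stage(s) {missing} enabled but 'simulate' is not: no upstream inputs"
            )
        if "stats" in stages:
            if not cfg.table_path:
                raise StageDependencyError(
                    "stats stage enabled without upstream pipeline: set table_path"
                )
            table = pd.read_csv(cfg.table_path)
            clus, assoc_rows = _stats_stage(
                table, cfg, out, int(rngs[5].integers(2**31))
            )
            log.append(f"stats: chosen k = {clus.k}, {len(assoc_rows)} associations tested")
            return _write_manifest(cfg, out, log, t_start)
        raise StageDependencyError("no stages enabled")

    # -- simulate -----------------------------------------------------------
    sim = _simulate_cohort(cfg, rngs[0])
    neurons = sim["neurons"]
    log.append(f"simulate: {len(neurons)} neurons, volume {sim['volume'].labels.shape}")

    # -- calcium ------------------------------------------------------------
    responsive = []
    for nr in neurons:
        nr["responsive"] = cal.is_responsive(
            nr["tensor"], threshold=cfg.responsive_threshold, min_repeats=cfg.min_repeats
        )
        if nr["responsive"]:
            nr["matrix"] = cal.build_response_matrix(nr["tensor"])
            responsive.append(nr)
    log.append(f"calcium: {len(responsive)}/{len(neurons)} responsive")

    # -- tune ---------------------------------------------------------------
    fit_seed = int(rngs[1].integers(2**31))
    rows = []
    for nr in responsive:
        osi = tq.compute_osi(nr["matrix"])
        fit = tq.fit_spatiotemporal(nr["matrix"], restarts=cfg.fit_restarts, seed=fit_seed)
        nr["osi"] = osi
        nr["fit"] = fit
        rows.append(
            {"neuron_id": nr["id"], "class_true": nr["class"], "osi": osi.osi,
             "osi_true": nr["spec"].osi_target, "r_pref": osi.r_pref,
             "r_ortho": osi.r_ortho, "A": fit.A, "sf0": fit.sf0, "tf0": fit.tf0,
             "sigma_sf": fit.sigma_sf, "sigma_tf": fit.sigma_tf, "xi": fit.xi,
             "r2": fit.r2}
        )
    tuning_df = pd.DataFrame(rows)
    tuning_df.to_csv(out / "tuning.csv", index=False)
    log.append(f"tune: {len(rows)} neurons fitted")

    # -- match --------------------------------------------------------------
    if "match" in stages:
        P1, P2 = sim["landmarks"]
        transform, residual, skipped = xmod.estimate_affine(xmod.LandmarkSet(P1=P1, P2=P2))
        soma_xy = np.array([nr["spec"].soma_xyz[:2] for nr in responsive])
        functional_xy = xmod.apply_affine(xmod.invert_affine(sim["true_affine"]), soma_xy)
        mapped = xmod.apply_affine(transform, functional_xy)
        result = xmod.match_cells(mapped, soma_xy, max_dist=cfg.match_max_dist)
        rates = xmod.bookkeeping_rates(
            n_responsive=len(responsive), n_matched=len(result.pairs),
            n_traced=len(result.pairs), n_in_vivo=len(neurons),
        )
        pd.DataFrame(
            [{"functional_id": responsive[i]["id"], "structural_id": responsive[j]["id"],
              "residual_px": d} for i, j, d in result.pairs]
        ).to_csv(out / "matching.csv", index=False)
        log.append(
            f"match: rate {result.matching_rate:.3f}, affine residual {residual:.2e}"
        )
        matched = [responsive[i] for i, _, _ in result.pairs]
        matching_rate = result.matching_rate
    else:
        matched = responsive
        rates = {}
        matching_rate = float("nan")
        log.append("match: skipped (stage disabled); all responsive neurons retained")

    # -- project ------------------------------------------------------------
    profiles = []
    for nr in matched:
        profile = proj.axon_length_by_region(
            nr["swc"], sim["volume"], step_um=cfg.step_um,
            threshold_mm=cfg.target_threshold_mm,
        )
        nr["profile"] = profile
        profiles.append(profile)
    cohort_stats = proj.multitarget_stats(profiles)
    log.append(
        f"project: {len(profiles)} profiles, median total "
        f"{cohort_stats['median_total_length_mm']:.2f} mm"
    )

    # -- quality ------------------------------------------------------------
    rng_q = rngs[4]
    sbr_values = []
    for nr in matched:
        baseline = rng_q.uniform(8.0, 15.0)
        peak = rng_q.uniform(60.0, 160.0)
        prof = baseline + rng_q.uniform(0.0, 2.0, sq.FIBER_PROFILE_LEN)
        prof[sq.FIBER_PROFILE_LEN // 2] = peak
        sbr_values.append(sq.compute_sbr(sq.FiberProfile(intensities=prof)))
    sampling = sq.select_sampling_points(matched[0]["swc"], interval_um=cfg.snr_interval_um)
    log.append(
        f"quality: mean SBR {np.mean(sbr_values):.2f}, "
        f"{len(sampling)} SNR sampling points on neuron {matched[0]['id']}"
    )

    # -- stats --------------------------------------------------------------
    regions = sorted({a for p in profiles for a in p.length_mm if a != proj.OUTSIDE_LABEL})
    table = pd.DataFrame(
        [{"neuron_id": nr["id"], "r2": nr["fit"].r2, "osi": nr["osi"].osi,
          "class_true": nr["class"],
          **{r: nr["profile"].length_mm.get(r, 0.0) for r in regions}}
         for nr in matched]
    )
    table.to_csv(out / "fawps_table.csv", index=False)
    clus, assoc_rows = _stats_stage(table, cfg, out, int(rngs[5].integers(2**31)))
    with open(out / "summary.json", "w") as fh:
        json.dump(
            {"matching_rate": matching_rate, "rates": rates,
             "cohort_stats": cohort_stats, "chosen_k": clus.k,
             "ch_by_k": {str(k): v for k, v in clus.ch_by_k.items()},
             "mean_sbr": float(np.mean(sbr_values))},
            fh, indent=2,
        )
    log.append(f"stats: chosen k = {clus.k}, {len(assoc_rows)} associations tested")
    return _write_manifest(cfg, out, log, t_start)
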