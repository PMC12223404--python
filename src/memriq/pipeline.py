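"""End-to-end orchestration: phantom cohorts, per-subject analysis, metrics.

A synthetic cohort mirrors a small ischemia–reperfusion study: IRI subjects
carry a lateral ischemic sector (the scar-designated subregion) whose true
extent is drawn per subject, plus a wider enhanced sector in the LGE volume
(area at risk strictly containing the scar); sham and naive subjects carry
neither.  Each subject is analyzed with all quantifiers — slope and
threshold perfusion deficits, LGE area at risk, cine volumetrics, segmental
fractional wall thickening, and a mean myocardial T1 from the VFA stack —
yielding one metrics row per subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .core import DynamicSeries, ImageVolume, LabelMap, SECTOR_NAMES
from .enhancement import septal_reference, threshold_fraction
from .function import (
    cavity_volume,
    ejection_fraction,
    fractional_wall_thickening,
    wall_thickness,
)
from .perfusion import deficit_from_slopes, pixel_slope_map, split_windows
from .phantom import (
    GroundTruth,
    PhantomSpec,
    UptakeKinetics,
    make_lv_labelmap,
    make_t1_truth,
    sector_width_for_fraction,
    simulate_cine,
    simulate_lge_volume,
    simulate_memri_dynamics,
    simulate_vfa_stack,
)
from .t1 import VFAStack, fit_t1_linear


@dataclass
class RunConfig:
    """Cohort and analysis settings.

    ``snr`` sets the additive noise level relative to the dynamic baseline
    (sigma = s0/snr); ``deficit_range_pct`` is the uniform interval the IRI
    subjects' true ischemic fractions are drawn from; ``aar_margin_deg`` is
    the extra angular width (per side) of the LGE-enhanced sector beyond the
    scar sector, making the area at risk strictly contain the scar.
    """

    n_iri: int = 7
    n_sham: int = 6
    n_naive: int = 3
    seed: int = 0
    snr: float | None = 40.0
    deficit_range_pct: tuple[float, float] = (15.0, 40.0)
    aar_margin_deg: float = 15.0
    t_occlusion_min: float = 30.0
    threshold_k: float = 2.0
    slope_mode: str = "endpoint"
    n_segments: int = 4
    n_cine_frames: int = 20
    flip_angles_deg: tuple[float, ...] = (2.0, 5.0, 8.0, 11.0, 14.0)
    tr_ms: float = 11.1
    te_ms: float = 2.3
    t1_myo_ms: dict = field(
        default_factory=lambda: {"IRI": 1490.0, "sham": 1487.0, "naive": 1487.0}
    )
    spec: PhantomSpec = field(default_factory=PhantomSpec)
    kinetics: UptakeKinetics = field(default_factory=UptakeKinetics)


@dataclass
class SubjectPhantom:
    """All simulated acquisitions plus truth for one synthetic subject."""

    subject_id: str
    group: str
    labels: LabelMap
    series: DynamicSeries
    series_truth: GroundTruth
    lge: ImageVolume
    lge_truth: GroundTruth
    cine: list[LabelMap]
    cine_truth: GroundTruth
    vfa: VFAStack
    t1_true_ms: float
    seed: int


def _subject_seeds(base_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(base_seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def make_subject(
    config: RunConfig,
    group: str,
    subject_id: str,
    seed: int,
    deficit_fraction_pct: float | None = None,
) -> SubjectPhantom:
    """Generate one subject's full set of synthetic acquisitions.

    IRI subjects get an ischemic lateral sector sized for
    ``deficit_fraction_pct`` and an LGE-enhanced sector wider by
    ``aar_margin_deg`` per side; other groups get neither.
    """
    kin = config.kinetics
    sigma_dyn = 0.0 if config.snr is None else kin.s0 / config.snr
    if group == "IRI":
        if deficit_fraction_pct is None:
            raise ValueError("IRI subjects need a target deficit fraction")
        scar_sector = sector_width_for_fraction(deficit_fraction_pct)
        aar_sector = (
            scar_sector[0] - config.aar_margin_deg,
            scar_sector[1] + config.aar_margin_deg,
        )
    else:
        scar_sector = None
        aar_sector = None
    spec = replace(
        config.spec,
        ischemic_sector_deg=scar_sector,
        noise_sigma=sigma_dyn,
        seed=seed,
    )
    labels = make_lv_labelmap(spec, "ED")
    series, series_truth = simulate_memri_dynamics(spec, kin)
    lge, lge_truth = simulate_lge_volume(replace(spec, seed=seed + 1), aar_sector)
    impaired = scar_sector if group == "IRI" else None
    cine, cine_truth = simulate_cine(spec, config.n_cine_frames, impaired_sector_deg=impaired)

    t1_true = config.t1_myo_ms[group]
    t1_vol, m0_vol = make_t1_truth(labels, t1_myo_ms=t1_true)
    # scale VFA noise to the mean myocardial signal so SNR means the same thing
    vfa_spec = replace(spec, seed=seed + 2, noise_sigma=0.0)
    clean = simulate_vfa_stack(vfa_spec, t1_vol, m0_vol, list(config.flip_angles_deg), config.tr_ms)
    if config.snr is not None:
        myo = labels.myocardium_mask()
        mean_sig = float(np.mean([v.data[myo].mean() for v in clean]))
        rng = np.random.default_rng(seed + 2)
        clean = [
            ImageVolume(v.data + rng.normal(0.0, mean_sig / config.snr, v.data.shape), v.voxel_size)
            for v in clean
        ]
    vfa = VFAStack(clean, list(config.flip_angles_deg), config.tr_ms, config.te_ms, labels)

    return SubjectPhantom(
        subject_id, group, labels, series, series_truth, lge, lge_truth,
        cine, cine_truth, vfa, t1_true, seed,
    )


def analyze_subject(subj: SubjectPhantom, config: RunConfig) -> dict:
    """Run every quantifier on one subject; returns one metrics row."""
    labels = subj.labels
    row: dict = {"subject_id": subj.subject_id, "group": subj.group, "seed": subj.seed}

    # perfusion deficit, slope criterion
    ischemia, _ = split_windows(subj.series, config.t_occlusion_min)
    smap = pixel_slope_map(ischemia, labels, "ischemia", config.slope_mode)
    row["deficit_slope_pct_lv"] = deficit_from_slopes(smap, labels).deficit_pct_lv

    # perfusion deficit, threshold criterion on the end-of-ischemia frame
    end_frame = ischemia.frames[-1]
    ref = septal_reference(end_frame, labels)
    row["deficit_threshold_pct_lv"] = threshold_fraction(
        end_frame, labels, ref, config.threshold_k, "below", "MEMRI"
    ).fraction_pct_lv

    # LGE area at risk
    ref_lge = septal_reference(subj.lge, labels)
    row["aar_pct_lv"] = threshold_fraction(
        subj.lge, labels, ref_lge, config.threshold_k, "above", "LGE"
    ).fraction_pct_lv

    # truth references
    row["deficit_true_pct_lv"] = subj.series_truth.deficit_fraction_true
    row["aar_true_pct_lv"] = subj.lge_truth.enhanced_fraction_true
    row["scar_pct_lv"] = subj.series_truth.deficit_fraction_true

    # volumetrics
    vols = [cavity_volume(m) for m in subj.cine]
    vr = ejection_fraction(vols)
    row["edv_ul"], row["esv_ul"], row["ef_pct"] = vr.edv_ul, vr.esv_ul, vr.ef_pct

    # segmental fWT on the mid-ventricular slice
    mid = labels.shape[2] // 2
    wt_ed = wall_thickness(subj.cine[vr.frame_ed], mid, config.n_segments)
    wt_es = wall_thickness(subj.cine[vr.frame_es], mid, config.n_segments)
    for seg in fractional_wall_thickening(wt_ed, wt_es):
        name = SEGMENT_NAME(seg.segment_id, config.n_segments)
        row[f"fwt_{name}_pct"] = seg.fwt_pct

    # native T1
    t1map = fit_t1_linear(subj.vfa)
    ok = t1map.fit_ok
    row["t1_mean_ms"] = float(np.nanmean(t1map.t1_ms[ok])) if ok.any() else np.nan
    row["t1_true_ms"] = subj.t1_true_ms
    return row


def SEGMENT_NAME(segment_id: int, n_segments: int) -> str:
    from .function import SEGMENT_NAMES_4

    if n_segments == 4:
        return SEGMENT_NAMES_4[segment_id]
    return f"seg{segment_id}"


def run_synthetic_cohort(config: RunConfig) -> tuple[pd.DataFrame, dict]:
    """Generate and analyze a full synthetic cohort.

    Returns the metrics table (one row per subject) and a manifest recording
    groups, per-subject seeds and drawn true fractions — rerunning with the
    same config reproduces the table exactly.
    """
    groups = (
        ["IRI"] * config.n_iri + ["sham"] * config.n_sham + ["naive"] * config.n_naive
    )
    seeds = _subject_seeds(config.seed, len(groups))
    frac_rng = np.random.default_rng(config.seed)
    lo, hi = config.deficit_range_pct
    rows = []
    manifest = {"seed": config.seed, "subjects": []}
    for i, (group, seed) in enumerate(zip(groups, seeds)):
        sid = f"{group}{i + 1:02d}"
        frac = float(frac_rng.uniform(lo, hi)) if group == "IRI" else None
        subj = make_subject(config, group, sid, seed, frac)
        rows.append(analyze_subject(subj, config))
        manifest["subjects"].append(
            {"subject_id": sid, "group": group, "seed": seed, "target_deficit_pct": frac}
        )
    return pd.DataFrame(rows), manifest


# ---------------------------------------------------------------------------
# on-disk subject layout (NIfTI + JSON sidecars)


def write_subject(subj: SubjectPhantom, out_dir: str | Path) -> None:
    """Persist one subject's acquisitions in the documented directory layout."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mio.save_labelmap(subj.labels, out / "labels.nii.gz", out / "sectors.nii.gz")
    mio.save_series(subj.series, out / "dynamic.nii.gz", out / "dynamic.json")
    mio.save_volume(subj.lge, out / "lge.nii.gz")
    cine_dir = out / "cine"
    cine_dir.mkdir(exist_ok=True)
    for k, m in enumerate(subj.cine):
        mio.save_labelmap(m, cine_dir / f"frame_{k:02d}.nii.gz")
    vfa_dir = out / "vfa"
    vfa_dir.mkdir(exist_ok=True)
    for alpha, vol in zip(subj.vfa.flip_angles_deg, subj.vfa.volumes):
        mio.save_volume(vol, vfa_dir / f"fa_{alpha:04.1f}.nii.gz")
    mio.save_json(
        {
            "flip_angles_deg": list(subj.vfa.flip_angles_deg),
            "tr_ms": subj.vfa.tr_ms,
            "te_ms": subj.vfa.te_ms,
        },
        vfa_dir / "vfa.json",
    )
    mio.save_json(
        {
            "subject_id": subj.subject_id,
            "group": subj.group,
            "seed": subj.seed,
            "deficit_fraction_true_pct": subj.series_truth.deficit_fraction_true,
            "enhanced_fraction_true_pct": subj.lge_truth.enhanced_fraction_true,
            "cavity_volume_true_ul": list(subj.cine_truth.cavity_volume_true_ul),
            "t1_true_ms": subj.t1_true_ms,
        },
        out / "truth.json",
    )


def run_subject(config: RunConfig, subject_dir: str | Path) -> dict:
    """Analyze a subject directory; missing modalities leave metrics absent.

    Expected layout (all optional except labels):
    ``labels.nii.gz`` + ``sectors.nii.gz``, ``dynamic.nii.gz`` +
    ``dynamic.json``, ``lge.nii.gz``, ``cine/frame_*.nii.gz``,
    ``vfa/fa_*.nii.gz`` + ``vfa/vfa.json``.
    """
    d = Path(subject_dir)
    row: dict = {"subject_id": d.name}
    labels = None
    if (d / "labels.nii.gz").exists():
        sector = d / "sectors.nii.gz"
        labels = mio.load_labelmap(d / "labels.nii.gz", sector if sector.exists() else None)

    if labels is not None and (d / "dynamic.nii.gz").exists():
        series = mio.load_series(d / "dynamic.nii.gz", d / "dynamic.json")
        ischemia, _ = split_windows(series, config.t_occlusion_min)
        smap = pixel_slope_map(ischemia, labels, "ischemia", config.slope_mode)
        row["deficit_slope_pct_lv"] = deficit_from_slopes(smap, labels).deficit_pct_lv
        end_frame = ischemia.frames[-1]
        ref = septal_reference(end_frame, labels)
        row["deficit_threshold_pct_lv"] = threshold_fraction(
            end_frame, labels, ref, config.threshold_k, "below", "MEMRI"
        ).fraction_pct_lv

    if labels is not None and (d / "lge.nii.gz").exists():
        lge = mio.load_volume(d / "lge.nii.gz")
        ref = septal_reference(lge, labels)
        row["aar_pct_lv"] = threshold_fraction(
            lge, labels, ref, config.threshold_k, "above", "LGE"
        ).fraction_pct_lv

    cine_files = sorted((d / "cine").glob("frame_*.nii.gz")) if (d / "cine").is_dir() else []
    if cine_files:
        maps = [mio.load_labelmap(p) for p in cine_files]
        vols = [cavity_volume(m) for m in maps]
        vr = ejection_fraction(vols)
        row["edv_ul"], row["esv_ul"], row["ef_pct"] = vr.edv_ul, vr.esv_ul, vr.ef_pct

    vfa_dir = d / "vfa"
    if labels is not None and vfa_dir.is_dir() and (vfa_dir / "vfa.json").exists():
        meta = mio.load_json(vfa_dir / "vfa.json")
        vols = [mio.load_volume(p) for p in sorted(vfa_dir.glob("fa_*.nii.gz"))]
        stack = VFAStack(vols, meta["flip_angles_deg"], meta["tr_ms"], meta.get("te_ms"), labels)
        t1map = fit_t1_linear(stack)
        ok = t1map.fit_ok
        row["t1_mean_ms"] = float(np.nanmean(t1map.t1_ms[ok])) if ok.any() else np.nan
    return row
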