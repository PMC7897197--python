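"""End-to-end pipeline: cohort synthesis -> pixelwise fitting -> statistics.

Two surfaces are provided.  The in-memory functions (:func:`fit_cohort`,
:func:`analyze_measurements`) run the whole chain without touching disk and
are what the examples, tests and acceptance instrumentation use.  The
``run_*`` stage functions mirror them on disk (NIfTI/CSV/JSON) and back the
``t1norm simulate / fit / analyze`` command-line interface, so exported
real-scanner series could later be fitted without the simulator.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import (
    BRAIN_REGION_NAMES,
    CohortConfig,
    Ellipse,
    RegionSpec,
    render_phantom,
    sample_subject,
    synthesize_series,
)
from .fitting import T1Map, fit_map
from .normative import NormativeFit, percentile_bands, select_model
from .reliability import bland_altman, icc_absolute, structure_contrasts
from .roi import extract_roi_stats, measurements_to_frame, pool_measurements, simulate_rater
from .signal_model import AcquisitionProtocol

__all__ = [
    "PipelineConfig",
    "fit_cohort",
    "subject_measurements",
    "analyze_measurements",
    "run_simulate",
    "run_fit",
    "run_analyze",
]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Resolved configuration of a full pipeline run."""

    protocol: AcquisitionProtocol
    cohort: CohortConfig
    fit_mode: str = "signed"
    rater_jitter_px: int = 1
    rater_erosion_px: int = 1
    pool_age_min: float = 5.0
    pool_age_max: float = 18.0

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        proto = AcquisitionProtocol(**d["protocol"])
        cd = dict(d["cohort"])
        if cd.get("regions"):
            cd["regions"] = tuple(
                RegionSpec(
                    **{
                        **r,
                        "ellipses": tuple(Ellipse(**e) for e in r["ellipses"]),
                    }
                )
                for r in cd["regions"]
            )
        if cd.get("ages") is not None:
            cd["ages"] = tuple(cd["ages"])
        cohort = CohortConfig(**cd)
        rest = {k: v for k, v in d.items() if k not in ("protocol", "cohort")}
        return cls(protocol=proto, cohort=cohort, **rest)


def _rater_rngs(cfg: CohortConfig, index: int):
    return (
        np.random.default_rng(np.random.SeedSequence([cfg.master_seed, index, 2])),
        np.random.default_rng(np.random.SeedSequence([cfg.master_seed, index, 3])),
    )


def subject_measurements(
    t1_map: T1Map | np.ndarray,
    labels: np.ndarray,
    pcfg: PipelineConfig,
    subject_id: str,
    index: int,
) -> list:
    """Extract both simulated raters' ROI records from one fitted map."""
    rng1, rng2 = _rater_rngs(pcfg.cohort, index)
    records = []
    for rater, rng in (("r1", rng1), ("r2", rng2)):
        perturbed = simulate_rater(
            labels, pcfg.rater_jitter_px, pcfg.rater_erosion_px, rng
        )
        records += extract_roi_stats(
            t1_map, perturbed, pcfg.cohort.regions, subject_id, rater=rater
        )
    return records


def fit_cohort(
    pcfg: PipelineConfig,
    subjects: range | None = None,
    progress: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthesize, fit and measure every subject in memory.

    Returns (measurements, ages): the tidy ROI table over both simulated
    raters and the subject age/truth table.
    """
    cfg = pcfg.cohort
    subjects = subjects if subjects is not None else range(cfg.n_subjects)
    all_records = []
    age_rows = []
    for i in subjects:
        t0 = time.perf_counter()
        subject = sample_subject(cfg, i)
        labels, _, _ = render_phantom(subject, cfg.regions, cfg)
        stack = synthesize_series(subject, pcfg.protocol, cfg)
        t1_map = fit_map(stack, pcfg.protocol, mode=pcfg.fit_mode)
        all_records += subject_measurements(t1_map, labels, pcfg, subject.subject_id, i)
        age_rows.append(
            {"subject_id": subject.subject_id, "age_years": subject.age_years,
             **{f"true_{k}": v for k, v in subject.true_t1_by_region.items()}}
        )
        log.info(
            "subject %s fitted in %.1f s (converged fraction %.3f)",
            subject.subject_id, time.perf_counter() - t0,
            t1_map.converged_fraction,
        )
        if progress:
            print(f"  {subject.subject_id}: {time.perf_counter() - t0:.1f} s")
    return measurements_to_frame(all_records), pd.DataFrame(age_rows)


def _per_subject_means(measurements: pd.DataFrame) -> pd.DataFrame:
    """Subject-level region means: sides averaged within rater, then raters."""
    per_rater = measurements.groupby(
        ["region", "subject_id", "rater"], as_index=False
    ).mean_t1_ms.mean()
    return per_rater.groupby(["region", "subject_id"], as_index=False).mean_t1_ms.mean()


def analyze_measurements(
    measurements: pd.DataFrame,
    ages: pd.DataFrame,
    pcfg: PipelineConfig,
    band_ages: np.ndarray | None = None,
) -> dict:
    """All downstream statistics from a measurements table.

    Returns a dict with: ``pooled`` (per-region pooled means over the
    configured age window), ``fits`` (selected normative model per region),
    ``bands`` (percentile-band curves), ``recovery`` (generator-vs-fit
    table), ``icc`` (inter-rater ICC(2,1) per region), ``intra_ba`` /
    ``inter_ba`` (Bland-Altman records) and ``contrasts`` (pairwise
    Wilcoxon p-value matrix over the brain structures).
    """
    regions = pcfg.cohort.regions
    pooled = pool_measurements(
        measurements, ages, pcfg.pool_age_min, pcfg.pool_age_max
    )
    per_subject = _per_subject_means(measurements).merge(
        ages[["subject_id", "age_years"]], on="subject_id"
    )

    fits: dict[str, NormativeFit] = {}
    bands = {}
    if band_ages is None:
        band_ages = np.linspace(0.2, 18.0, 90)
    for region in regions:
        sub = per_subject[per_subject.region == region.name]
        if len(sub) < 4:
            continue
        fit = select_model(sub.age_years.to_numpy(), sub.mean_t1_ms.to_numpy(),
                           region=region.name)
        fits[region.name] = fit
        bands[region.name] = percentile_bands(fit, band_ages)

    from .normative import parameter_recovery_report

    recovery = parameter_recovery_report(regions, fits)

    icc = {}
    inter_ba = {}
    intra_ba = {}
    for region in regions:
        sub = measurements[measurements.region == region.name]
        rater_means = sub.groupby(["subject_id", "rater"]).mean_t1_ms.mean().unstack()
        if rater_means.shape[1] == 2 and not rater_means.isna().any().any():
            icc[region.name] = icc_absolute(rater_means)
            inter_ba[region.name] = bland_altman(
                rater_means.iloc[:, 0], rater_means.iloc[:, 1]
            )
        sides = sub[sub.side.isin(["left", "right"])]
        if not sides.empty:
            lr = sides.groupby(["subject_id", "side"]).mean_t1_ms.mean().unstack()
            if lr.shape[1] == 2 and not lr.isna().any().any():
                intra_ba[region.name] = bland_altman(lr["left"], lr["right"])

    contrasts = structure_contrasts(
        per_subject[per_subject.region.isin(BRAIN_REGION_NAMES)]
    )
    return {
        "pooled": pooled,
        "per_subject": per_subject,
        "fits": fits,
        "bands": bands,
        "recovery": recovery,
        "icc": icc,
        "inter_ba": inter_ba,
        "intra_ba": intra_ba,
        "contrasts": contrasts,
    }


# ---------------------------------------------------------------------------
# Disk stages (CLI backends)
# ---------------------------------------------------------------------------

def run_simulate(pcfg: PipelineConfig, out_dir: str | Path) -> dict:
    """Stage 1: write the synthetic cohort (series, labels, truth, manifest)."""
    from .cohort import generate_cohort

    out = Path(out_dir)
    manifest = generate_cohort(pcfg.cohort, pcfg.protocol, out)
    manifest["pipeline_config"] = pcfg.to_dict()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _load_pcfg(in_dir: Path) -> PipelineConfig:
    manifest = json.loads((in_dir / "manifest.json").read_text())
    return PipelineConfig.from_dict(manifest["pipeline_config"])


def run_fit(in_dir: str | Path, mode: str | None = None, force: bool = False) -> None:
    """Stage 2: fit a T1 map per subject series found in ``in_dir``.

    Existing outputs are skipped unless ``force``.  Each map gets a NIfTI
    value/mask pair and a JSON sidecar recording protocol, mode and solver
    settings.
    """
    import nibabel as nib

    in_dir = Path(in_dir)
    pcfg = _load_pcfg(in_dir)
    mode = mode or pcfg.fit_mode
    from .fitting import BACKGROUND_FRACTION, T1_WINDOW_MS

    for series_path in sorted(in_dir.glob("sub*_series.nii")):
        sid = series_path.name.split("_")[0]
        map_path = in_dir / f"{sid}_t1map.nii"
        if map_path.exists() and not force:
            log.info("%s: map exists, skipping (use --force to refit)", sid)
            continue
        t0 = time.perf_counter()
        img = nib.load(series_path)
        stack = np.transpose(np.asarray(img.dataobj)[:, :, 0, :], (2, 0, 1))
        t1_map = fit_map(stack, pcfg.protocol, mode=mode)
        affine = img.affine
        nib.save(nib.Nifti1Image(
            t1_map.values[:, :, None].astype(np.float32), affine), map_path)
        nib.save(nib.Nifti1Image(
            t1_map.mask[:, :, None].astype(np.uint8), affine),
            in_dir / f"{sid}_t1mask.nii")
        sidecar = {
            "protocol": json.loads(pcfg.protocol.to_json()),
            "mode": mode,
            "t1_window_ms": list(T1_WINDOW_MS),
            "background_fraction": BACKGROUND_FRACTION,
            "converged_fraction": t1_map.converged_fraction,
        }
        (in_dir / f"{sid}_t1map.json").write_text(json.dumps(sidecar, indent=2))
        log.info("%s: fitted in %.1f s (converged fraction %.3f)",
                 sid, time.perf_counter() - t0, sidecar["converged_fraction"])


def run_analyze(in_dir: str | Path, age_min: float | None = None,
                age_max: float | None = None) -> dict:
    """Stage 3: ROI extraction (two simulated raters), pooling, normative
    fits with bands, and reliability statistics; writes CSVs + summary.json.
    """
    import nibabel as nib

    in_dir = Path(in_dir)
    pcfg = _load_pcfg(in_dir)
    if age_min is not None:
        pcfg.pool_age_min = age_min
    if age_max is not None:
        pcfg.pool_age_max = age_max
    truth = pd.read_csv(in_dir / "truth.csv")
    ages = truth[["subject_id", "age_years"]].drop_duplicates().reset_index(drop=True)

    records = []
    for map_path in sorted(in_dir.glob("sub*_t1map.nii")):
        sid = map_path.name.split("_")[0]
        values = np.asarray(nib.load(map_path).dataobj)[:, :, 0].astype(float)
        mask = np.asarray(
            nib.load(in_dir / f"{sid}_t1mask.nii").dataobj)[:, :, 0].astype(bool)
        labels = np.asarray(
            nib.load(in_dir / f"{sid}_labels.nii").dataobj)[:, :, 0].astype(np.int16)
        t1_map = T1Map(values, mask, pcfg.protocol)
        records += subject_measurements(t1_map, labels, pcfg, sid, int(sid[3:]))
    measurements = measurements_to_frame(records)
    result = analyze_measurements(measurements, ages, pcfg)

    ff = "%.6f"
    measurements.to_csv(in_dir / "measurements.csv", index=False, float_format=ff)
    fit_rows = [
        {"region": name, **{k: v for k, v in f.__dict__.items() if k != "region"}}
        for name, f in result["fits"].items()
    ]
    pd.DataFrame(fit_rows).to_csv(in_dir / "normative_fits.csv", index=False,
                                  float_format=ff)
    pd.concat(
        [b.assign(region=name) for name, b in result["bands"].items()]
    ).to_csv(in_dir / "percentile_bands.csv", index=False, float_format=ff)
    result["recovery"].to_csv(in_dir / "parameter_recovery.csv", index=False,
                              float_format=ff)
    result["contrasts"].to_csv(in_dir / "structure_contrasts.csv", float_format="%.3e")
    rel_rows = []
    for name, r in result["icc"].items():
        rel_rows.append({"region": name, "metric": "icc_2_1", "value": r.icc_value})
    for kind in ("inter_ba", "intra_ba"):
        for name, r in result[kind].items():
            rel_rows.append({"region": name, "metric": f"{kind}_bias_ms",
                             "value": r.bias_ms})
            rel_rows.append({"region": name, "metric": f"{kind}_loa_low_ms",
                             "value": r.loa_low_ms})
            rel_rows.append({"region": name, "metric": f"{kind}_loa_high_ms",
                             "value": r.loa_high_ms})
    pd.DataFrame(rel_rows).to_csv(in_dir / "reliability.csv", index=False,
                                  float_format=ff)
    summary = {
        "pooled_mean_t1_ms": {k: round(v, 3) for k, v in result["pooled"].items()},
        "pool_age_window": [pcfg.pool_age_min, pcfg.pool_age_max],
        "selected_family": {k: f.family for k, f in result["fits"].items()},
        "adj_r2": {k: round(f.adj_r2, 4) for k, f in result["fits"].items()},
        "fitted_n": {k: f.n_tenths for k, f in result["fits"].items()},
        "age_independent": {k: f.age_independent for k, f in result["fits"].items()},
        "icc_2_1": {k: round(r.icc_value, 4) for k, r in result["icc"].items()},
        "max_pairwise_contrast_p": float(np.nanmax(result["contrasts"].to_numpy())),
    }
    (in_dir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
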