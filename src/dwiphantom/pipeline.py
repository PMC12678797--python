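"""End-to-end orchestration: simulate -> resample -> ADC -> metrics -> GDR -> statistics.

``run_full_analysis`` is deterministic given the master seed and writes every
intermediate it computes (optionally the NIfTI volumes, always the tidy CSV
tables) plus a JSON report whose bytes depend only on the configuration and
seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import dwiphantom
from dwiphantom.acquisition import AcquisitionProtocol, sequence_preset, simulate_series
from dwiphantom.adc import CorrectionConstants, adc_roi_summary, compute_adc_map
from dwiphantom.phantom import PhantomSpec, build_phantom, compact_phantom, default_phantom
from dwiphantom.preprocess import ResampleSpec, resample_bilinear
from dwiphantom.ratings import CRITERIA, load_ratings_csv, rating_vectors, reference_rating_table
from dwiphantom.reference import RSEPI_SI_TABLE, rsepi_si_frame
from dwiphantom.roi import (
    ROISpec,
    default_rois,
    metric_table,
    metrics_to_frame,
    recon,
    summary_to_frame,
)
from dwiphantom.stats import (
    kruskal_wallis,
    percent_agreement,
    spearman_classified,
    weighted_kappa,
    wilcoxon_pairwise,
)

METRICS = ("ADC20", "SNR", "CNR", "ReCon", "GDR")
REPORT_DECIMALS = {"ADC20": 2, "SNR": 2, "CNR": 2, "ReCon": 2, "GDR": 2}


@dataclass(frozen=True)
class RunConfig:
    """Everything a full analysis run depends on."""

    phantom: PhantomSpec = field(default_factory=default_phantom)
    sequence_ids: tuple[str, ...] = ("ssEPI", "rsEPI", "TGSE_BLADE")
    n_repeats: int = 10
    analysis_pixel: float = 0.5  # mm, common grid after bilinear resampling
    include_2mm: bool = False
    kappa_weights: str = "linear"
    spearman_mode: str = "per_repeat"  # or "means"
    edge_rule: str = "min_times_1.10"
    master_seed: int = 0
    out_dir: Path = Path("results/run")
    write_volumes: bool = False
    ratings_csv: Path | None = None
    protocol_overrides: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.spearman_mode not in ("per_repeat", "means"):
            raise ValueError(f"unknown spearman_mode {self.spearman_mode!r}")
        labels = {f"{l.diameter:g}mm" for l in self.phantom.lesions}
        for seq_overrides in self.protocol_overrides.values():
            for key in seq_overrides:
                if key == "lesion_labels":
                    missing = set(seq_overrides[key]) - labels
                    if missing:
                        raise ValueError(f"unknown lesion labels {sorted(missing)}")

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        phantom = _phantom_from_dict(raw.pop("phantom", {}))
        out_dir = Path(raw.pop("out_dir", "results/run"))
        ratings = raw.pop("ratings_csv", None)
        return cls(phantom=phantom, out_dir=out_dir,
                   ratings_csv=Path(ratings) if ratings else None, **raw)

    def fingerprint(self) -> str:
        """Stable hash of the configuration (provenance for the report)."""
        payload = json.dumps(_config_dict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _phantom_from_dict(d: dict) -> PhantomSpec:
    from dwiphantom.phantom import LesionSpec

    kwargs = dict(d)
    lesions = kwargs.pop("lesions", None)
    if lesions is not None:
        kwargs["lesions"] = tuple(
            LesionSpec(diameter=l["diameter"], center=tuple(l["center"]),
                       adc_true=l.get("adc_true", 0.5e-3))
            for l in lesions
        )
    return PhantomSpec(**kwargs)


def _config_dict(config: RunConfig) -> dict:
    return {
        "phantom": {
            "cylinder_diameter": config.phantom.cylinder_diameter,
            "pixel_size_native": config.phantom.pixel_size_native,
            "slice_thickness": config.phantom.slice_thickness,
            "lesions": [
                {"diameter": l.diameter, "center": list(l.center), "adc_true": l.adc_true}
                for l in config.phantom.lesions
            ],
        },
        "sequence_ids": list(config.sequence_ids),
        "n_repeats": config.n_repeats,
        "analysis_pixel": config.analysis_pixel,
        "include_2mm": config.include_2mm,
        "kappa_weights": config.kappa_weights,
        "spearman_mode": config.spearman_mode,
        "edge_rule": config.edge_rule,
        "master_seed": config.master_seed,
        "protocol_overrides": config.protocol_overrides,
    }


def _resample_series(series, target_pixel: float):
    """Bilinear-resample every volume of a series to the analysis grid."""
    from dataclasses import replace as dc_replace

    native = series.repeats[0][0].pixel_size
    if np.isclose(native, target_pixel):
        return series
    spec = ResampleSpec(source_pixel=native, target_pixel=target_pixel)
    repeats = tuple(
        (resample_bilinear(b0, spec), resample_bilinear(b1000, spec))
        for b0, b1000 in series.repeats
    )
    # ground truth re-rasterized on the analysis grid for ROI placement
    return dc_replace(series, repeats=repeats)


@dataclass
class RunReport:
    config_hash: str
    master_seed: int
    version: str
    metric_summary: pd.DataFrame
    metric_long: pd.DataFrame
    homogeneous_adc: pd.DataFrame
    tests: pd.DataFrame
    correlations: pd.DataFrame
    kappa: pd.DataFrame | None

    def to_json(self) -> str:
        payload = {
            "provenance": {
                "config_hash": self.config_hash,
                "master_seed": self.master_seed,
                "software_version": self.version,
            },
            "metric_summary": _frame_records(self.metric_summary),
            "homogeneous_adc": _frame_records(self.homogeneous_adc),
            "tests": _frame_records(self.tests),
            "correlations": _frame_records(self.correlations),
            "kappa": _frame_records(self.kappa) if self.kappa is not None else None,
        }
        return json.dumps(payload, indent=2, sort_keys=True, allow_nan=True,
                          default=_json_default) + "\n"


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _frame_records(frame: pd.DataFrame) -> list[dict]:
    out = []
    for rec in frame.to_dict(orient="records"):
        clean = {}
        for k, v in rec.items():
            if isinstance(v, float):
                clean[k] = None if not np.isfinite(v) else round(v, 6)
            else:
                clean[k] = v
        out.append(clean)
    return out


def run_full_analysis(config: RunConfig) -> RunReport:
    """Run the whole pipeline and write intermediates + report under config.out_dir."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- simulate and resample each sequence --------------------------------
    series_by_seq = {}
    grids_analysis = None
    for k, seq_id in enumerate(config.sequence_ids):
        overrides = dict(config.protocol_overrides.get(seq_id, {}))
        protocol = sequence_preset(seq_id, n_repeats=config.n_repeats, **overrides)
        grids = build_phantom(config.phantom, "lesion_insert")
        seed = int(np.random.SeedSequence([config.master_seed, k]).generate_state(1)[0] % (2**31))
        series = simulate_series(grids, protocol, master_seed=seed)
        series = _resample_series(series, config.analysis_pixel)
        series_by_seq[seq_id] = series
        if grids_analysis is None:
            grids_analysis = build_phantom(config.phantom, "lesion_insert",
                                           pixel_size=config.analysis_pixel)
        if config.write_volumes:
            from dwiphantom.io import write_series
            write_series(series, out / "volumes", seq_id, master_seed=seed)

    # ROI set on the analysis grid (ground-truth centers, spec volumes)
    rois = default_rois(grids_analysis, include_2mm=config.include_2mm)
    # the resampled series carry the native-grid ground truth; patch in the
    # analysis-grid rasterization so ROI/GDR geometry matches the pixels
    from dataclasses import replace as dc_replace
    series_by_seq = {
        sid: dc_replace(s, ground_truth=grids_analysis) for sid, s in series_by_seq.items()
    }

    # --- homogeneous-compartment ADC accuracy -------------------------------
    homog_rows = []
    constants = CorrectionConstants()
    for comp, kind, truth in (("GM_control", "GM_control", 0.8),
                              ("RD_control", "RD_control", 0.5)):
        grids_c = build_phantom(config.phantom, comp, pixel_size=config.analysis_pixel)
        for k, seq_id in enumerate(config.sequence_ids):
            overrides = dict(config.protocol_overrides.get(seq_id, {}))
            protocol = sequence_preset(seq_id, n_repeats=config.n_repeats, **overrides)
            seed = int(
                np.random.SeedSequence([config.master_seed, 100 + k]).generate_state(1)[0]
                % (2**31)
            )
            series_c = simulate_series(grids_c, protocol, master_seed=seed)
            adc_maps = [compute_adc_map(b0, b1000) for b0, b1000 in series_c.repeats]
            roi = ROISpec(comp, (0.0, 0.0), 74.0, config.phantom.slice_thickness)
            summary = adc_roi_summary(adc_maps, roi, constants, kind)
            homog_rows.append(dict(compartment=comp, sequence=seq_id,
                                   mean=summary.mean, sd=summary.sd,
                                   min=summary.min, max=summary.max,
                                   reference=truth))
    homogeneous = pd.DataFrame(homog_rows)

    # --- lesion metric table -------------------------------------------------
    results = metric_table(series_by_seq, rois, include_2mm=config.include_2mm)
    summary = summary_to_frame(results)
    long = metrics_to_frame(results)

    # --- sequence comparisons ------------------------------------------------
    test_rows = []
    for metric in METRICS:
        pooled = {}
        for sid in config.sequence_ids:
            mask = (long["metric"] == metric) & (long["sequence"] == sid) & (long["lesion"] != "all")
            pooled[sid] = long[mask].sort_values(["lesion", "repeat"])["value"].to_numpy()
        if any(np.isnan(v).any() or v.size == 0 for v in pooled.values()):
            continue
        kw = kruskal_wallis(list(pooled.values()))
        test_rows.append(dict(metric=metric, comparison="kruskal_wallis",
                              statistic=kw.statistic, p=kw.p_value,
                              degenerate=kw.degenerate))
        for sa, sb in combinations(config.sequence_ids, 2):
            w = wilcoxon_pairwise(pooled[sa], pooled[sb])
            test_rows.append(dict(metric=metric, comparison=f"wilcoxon:{sa}-vs-{sb}",
                                  statistic=w.statistic, p=w.p_value,
                                  degenerate=w.degenerate))
    tests = pd.DataFrame(test_rows)

    # --- lesion-size correlations -------------------------------------------
    corr_rows = []
    for metric in ("SNR", "CNR", "GDR", "ReCon", "ADC20"):
        for sid in config.sequence_ids:
            sub = long[(long["metric"] == metric) & (long["sequence"] == sid)
                       & (long["lesion"] != "all")]
            if sub.empty or sub["value"].isna().any():
                continue
            diam = sub["lesion"].str.replace("mm", "", regex=False).astype(float)
            if config.spearman_mode == "means":
                grouped = sub.groupby(diam)["value"].mean()
                x, y = grouped.index.to_numpy(), grouped.to_numpy()
            else:
                x, y = diam.to_numpy(), sub["value"].to_numpy()
            try:
                c = spearman_classified(x, y)
            except ValueError:
                continue
            corr_rows.append(dict(metric=metric, sequence=sid, rho=c.rho,
                                  p=c.p_value, strength=c.strength_class))
    correlations = pd.DataFrame(corr_rows)

    # --- rater agreement -----------------------------------------------------
    kappa_frame = None
    if config.ratings_csv is not None:
        table = load_ratings_csv(config.ratings_csv)
        k_rows = []
        for criterion in sorted(table["criterion"].unique()):
            r1, r2 = rating_vectors(table, criterion)
            kres = weighted_kappa(r1, r2, weights=config.kappa_weights)
            pct, _ = percent_agreement(r1, r2)
            k_rows.append(dict(criterion=criterion, kappa=kres.kappa,
                               ci_low=kres.ci95[0], ci_high=kres.ci95[1],
                               altman=kres.altman, percent_agreement=pct,
                               degenerate=kres.degenerate))
        kappa_frame = pd.DataFrame(k_rows)

    report = RunReport(
        config_hash=config.fingerprint(),
        master_seed=config.master_seed,
        version=dwiphantom.__version__,
        metric_summary=summary,
        metric_long=long,
        homogeneous_adc=homogeneous,
        tests=tests,
        correlations=correlations,
        kappa=kappa_frame,
    )

    long.to_csv(out / "metrics_long.csv", index=False)
    summary.to_csv(out / "metrics_summary.csv", index=False)
    homogeneous.to_csv(out / "homogeneous_adc.csv", index=False)
    tests.to_csv(out / "statistics.csv", index=False)
    correlations.to_csv(out / "correlations.csv", index=False)
    if kappa_frame is not None:
        kappa_frame.to_csv(out / "rater_agreement.csv", index=False)
    (out / "report.json").write_text(report.to_json())
    return report


def make_fixture_suite(out_dir: Path, seed: int = 0) -> dict[str, Path]:
    """Emit small, fast-running fixtures: noiseless + noisy series, ratings, SI table."""
    from dwiphantom.io import write_series

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    spec = compact_phantom()
    grids = build_phantom(spec, "lesion_insert")

    clean_protocol = AcquisitionProtocol(
        sequence_id="custom", noise_sigma=0.0, n_repeats=3,
        temperature_schedule=(20.0, 20.0, 20.0), couple_adc_to_temperature=False,
    )
    clean = simulate_series(grids, clean_protocol, master_seed=seed)
    paths["noiseless_series"] = write_series(clean, out / "noiseless", "clean", seed)

    for k, seq_id in enumerate(("ssEPI", "rsEPI", "TGSE_BLADE")):
        protocol = sequence_preset(seq_id, n_repeats=3)
        series = simulate_series(grids, protocol, master_seed=seed + k + 1)
        paths[f"noisy_{seq_id}"] = write_series(series, out / "noisy", seq_id, seed + k + 1)

    ratings = reference_rating_table()
    ratings_path = out / "ratings.csv"
    ratings.to_csv(ratings_path, index=False)
    paths["ratings"] = ratings_path

    si = rsepi_si_frame()
    si["recon"] = [round(recon(r, g), 2) for r, g in zip(si["si_roi"], si["si_gm"])]
    si_path = out / "rsepi_si_recon.csv"
    si.to_csv(si_path, index=False)
    paths["si_table"] = si_path
    return paths
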