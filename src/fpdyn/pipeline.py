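"""End-to-end orchestration: config, generation, analyses, report tables.

``run_pipeline`` chains the synthetic generator (or, in principle, any
Trajectory source honouring the same contract) through every analysis stage
and writes one TSV per module operation plus a manifest recording the
config hash and a digest of every output file.  Output is a pure function
of (config, seed): rerunning the same config reproduces the manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .geometry import histogram, pair_distance_series, rmsd_series, rmsf, delta_rmsf
from .hbond import HBondCriteria, count_partitioned
from .io import (
    default_regions,
    load_regions,
    write_histogram_tsv,
    write_profile_tsv,
    write_series_tsv,
)
from .model import AtomSelection, RegionSet
from .states import flip_angle, segment_states
from .synthetic import (
    TitrationSpec,
    TrajectorySpec,
    WaterPlant,
    gen_titration,
    gen_trajectory,
    study_run_spec,
)
from .titration import (
    HIGH_RANGE_WINDOW,
    HIGH_REF_WAVELENGTH,
    LOW_RANGE_WINDOW,
    LOW_REF_WAVELENGTH,
    MAIN_PEAK_MCHERRY,
    MAIN_PEAK_MCORAL,
    default_mcherry_basis,
    default_mcherry_model,
    fit_pka,
    ratio_curve,
)
from .water import (
    ResidencyCriteria,
    aggregate_residency,
    classify_exit,
    distance_trace,
    format_residency,
    residency_time,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass(frozen=True)
class RunConfig:
    """Declarative pipeline configuration (YAML-loadable; flags may override)."""

    out_dir: str = "results/pipeline"
    seed: int = 0
    variants: tuple[str, ...] = ("mcoral", "mcherry")
    n_runs: int = 3
    duration_ns: float = 20.0
    frame_interval_ns: float = 0.01
    noise_sd_nm: float = 0.01
    water_plants: tuple[WaterPlant, ...] | None = None  # overrides the presets
    regions_path: str | None = None
    residency: ResidencyCriteria = field(default_factory=ResidencyCriteria)
    hbond: HBondCriteria = field(default_factory=HBondCriteria)
    hbond_water_schedule: tuple[tuple[float, int], ...] = ((0.0, 0),)
    hbond_protein_schedule: tuple[tuple[float, int], ...] = ((0.0, 0),)
    histogram_bin_nm: float = 0.1
    titration: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        plants = raw.pop("water_plants", None)
        if plants is not None:
            raw["water_plants"] = tuple(
                WaterPlant(
                    label=p["label"],
                    exit_time_ns=p.get("exit_time_ns"),
                    exit_region=p.get("exit_region"),
                )
                for p in plants
            )
        for key in ("variants", "hbond_water_schedule", "hbond_protein_schedule"):
            if key in raw:
                raw[key] = tuple(tuple(x) if isinstance(x, list) else x for x in raw[key])
        if "residency" in raw:
            raw["residency"] = ResidencyCriteria(**raw["residency"])
        if "hbond" in raw:
            raw["hbond"] = HBondCriteria(**raw["hbond"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["residency"] = {
            "cutoff_nm": self.residency.cutoff_nm,
            "persistence_ns": self.residency.persistence_ns,
        }
        d["hbond"] = dataclasses.asdict(self.hbond)
        if self.water_plants is not None:
            d["water_plants"] = [dataclasses.asdict(p) for p in self.water_plants]
        return d


def _validate(config: RunConfig, regions: RegionSet) -> None:
    for v in config.variants:
        if v not in ("mcoral", "mcherry"):
            raise PipelineError(f"validation: unknown variant {v!r}")
    plants = config.water_plants or ()
    for p in plants:
        if p.exit_region is not None and p.exit_region not in regions.labels:
            raise PipelineError(
                f"validation: water {p.label} references missing region {p.exit_region!r}"
            )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


_CA_SEL = AtomSelection(name="CA", chain="A")
_CRO_HEAVY = AtomSelection(res_id=(65, 66), predicate=lambda a: a.element != "H")
_PROTEIN_NOT_CRO = AtomSelection(chain="A", predicate=lambda a: a.res_id not in (65, 66))
_WATER_SEL = AtomSelection(res_name="HOH")


def _variant_spec(config: RunConfig, variant: str, run: int) -> TrajectorySpec:
    if config.water_plants is not None:
        return TrajectorySpec(
            duration_ns=config.duration_ns,
            frame_interval_ns=config.frame_interval_ns,
            noise_sd_nm=config.noise_sd_nm,
            water_plants=config.water_plants,
            hbond_water_schedule=config.hbond_water_schedule,
            hbond_protein_schedule=config.hbond_protein_schedule,
            seed=(config.seed * 31 + run) % (2**31),
        )
    spec = study_run_spec(
        variant,
        run,
        seed=config.seed,
        duration_ns=config.duration_ns,
        frame_interval_ns=config.frame_interval_ns,
        noise_sd_nm=config.noise_sd_nm,
    )
    return dataclasses.replace(
        spec,
        hbond_water_schedule=config.hbond_water_schedule,
        hbond_protein_schedule=config.hbond_protein_schedule,
    )


def _analyse_run(
    config: RunConfig,
    variant: str,
    run: int,
    regions: RegionSet,
    out: Path,
) -> tuple[list, "np.ndarray | None", object]:
    """Returns (residency records, per-residue RMSF profile, truth)."""
    spec = _variant_spec(config, variant, run)
    traj, truth = gen_trajectory(spec)
    res_id_of = {lb: 300 + i for i, lb in enumerate(truth.waters)}

    records = []
    with open(out / "residency.tsv", "w") as fh:
        fh.write("water_id\tresidency_ns\tcensored\texit_region\tdecision_margin_nm\n")
        for label in truth.waters:
            trace = distance_trace(traj, res_id_of[label], config.residency)
            rec = residency_time(trace, config.residency, water_id=label)
            if not rec.censored:
                rec = classify_exit(traj, res_id_of[label], rec, regions)
            records.append(rec)
            fh.write(
                f"{label}\t{format_residency(rec, traj.duration_ns)}\t"
                f"{int(rec.censored)}\t{rec.exit_region or 'N/A'}\t"
                f"{'' if rec.decision_margin_nm is None else f'{rec.decision_margin_nm:.3f}'}\n"
            )

    profile = rmsf(traj, _CA_SEL, _CA_SEL, per_residue=True)
    write_profile_tsv(out / "rmsf_ca.tsv", profile.keys, profile.values)

    series = rmsd_series(traj, traj.frame(0), _CA_SEL, _CRO_HEAVY, label="cro_rmsd")
    write_series_tsv(out / "cro_rmsd.tsv", series.times, series.values, "rmsd_nm")
    seg = segment_states(series)
    fl = flip_angle(traj)
    with open(out / "states.json", "w") as fh:
        json.dump(
            {
                "occupancy": seg.occupancy,
                "switch_count": seg.switch_count,
                "levels": seg.levels,
                "flip_events_ns": [float(traj.times[i]) for i in fl.events],
            },
            fh,
            indent=1,
        )

    counts = count_partitioned(
        traj,
        AtomSelection(res_id=(65, 66)),
        {"protein": _PROTEIN_NOT_CRO, "water": _WATER_SEL},
        config.hbond,
    )
    with open(out / "hbond_counts.tsv", "w") as fh:
        fh.write("time_ns\tcount_protein\tcount_water\n")
        for t, cp, cw in zip(counts.times, counts.counts["protein"], counts.counts["water"]):
            fh.write(f"{t:.6g}\t{cp}\t{cw}\n")
    for cls in ("protein", "water"):
        with open(out / f"hbond_freq_{cls}.tsv", "w") as fh:
            fh.write("count\tframes\n")
            for k, v in sorted(counts.frequency_table(cls).items()):
                fh.write(f"{k}\t{v}\n")

    for name, (ra, rb) in {
        "a145_k198": (145, 198),
        "t43_y214": (43, 214),
    }.items():
        d = pair_distance_series(
            traj,
            AtomSelection(name="CA", res_id=ra),
            AtomSelection(name="CA", res_id=rb),
            label=name,
        )
        write_series_tsv(out / f"dist_{name}.tsv", d.times, d.values, "distance_nm")
        h = histogram(d, config.histogram_bin_nm)
        write_histogram_tsv(out / f"hist_{name}.tsv", h.centers, h.counts)

    return records, profile, truth


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis chain; returns the manifest dictionary."""
    out_root = Path(config.out_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    regions = (
        load_regions(config.regions_path) if config.regions_path else default_regions()
    )
    _validate(config, regions)

    profiles: dict[str, object] = {}
    for variant in config.variants:
        all_records = []
        for run in range(1, config.n_runs + 1):
            out = out_root / variant / f"run{run}"
            out.mkdir(parents=True, exist_ok=True)
            stage = f"{variant}/run{run}"
            try:
                records, profile, _ = _analyse_run(config, variant, run, regions, out)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {stage} failed: {exc}") from exc
            log.info("stage %s complete (%d residency records)", stage, len(records))
            all_records.extend(records)
            profiles[variant] = profile  # last run's profile per variant
        summary = aggregate_residency(all_records)
        with open(out_root / variant / "residency_summary.tsv", "w") as fh:
            fh.write("water_id\tn\tmean_ns\tsd_ns\tn_censored\n")
            for row in summary.rows:
                mean = "" if row.mean_ns is None else f"{row.mean_ns:.6g}"
                sd = "" if row.sd_ns is None else f"{row.sd_ns:.6g}"
                fh.write(f"{row.water_id}\t{row.n}\t{mean}\t{sd}\t{row.n_censored}\n")

    if len(config.variants) == 2 and all(v in profiles for v in config.variants):
        a, b = (profiles[v] for v in config.variants)
        try:
            d = delta_rmsf(b, a)  # second minus first (e.g. mCherry - mCoral)
            write_profile_tsv(out_root / "delta_rmsf_ca.tsv", d.keys, d.values,
                              "delta_rmsf_nm")
        except ValueError:
            log.warning("delta RMSF skipped: profiles have differing keys")

    if config.titration:
        try:
            fits = {}
            series, _ = gen_titration(TitrationSpec(seed=config.seed))
            low = fit_pka(ratio_curve(series, MAIN_PEAK_MCORAL, LOW_REF_WAVELENGTH,
                                      window=LOW_RANGE_WINDOW))
            high = fit_pka(ratio_curve(series, MAIN_PEAK_MCORAL, HIGH_REF_WAVELENGTH,
                                       window=HIGH_RANGE_WINDOW))
            fits["mcoral"] = {"pka_low": low.pka, "pka_high": high.pka}
            series2, _ = gen_titration(
                TitrationSpec(model=default_mcherry_model(),
                              basis=default_mcherry_basis(), seed=config.seed)
            )
            single = fit_pka(ratio_curve(series2, MAIN_PEAK_MCHERRY, LOW_REF_WAVELENGTH))
            fits["mcherry"] = {"pka": single.pka}
            with open(out_root / "pka_fits.json", "w") as fh:
                json.dump(fits, fh, indent=1)
        except Exception as exc:
            raise PipelineError(f"stage titration failed: {exc}") from exc

    config_json = json.dumps(config.to_dict(), sort_keys=True)
    files = sorted(
        str(p.relative_to(out_root))
        for p in out_root.rglob("*")
        if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "outputs": {f: _sha256(out_root / f) for f in files},
    }
    with open(out_root / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
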