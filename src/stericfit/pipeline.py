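"""End-to-end orchestration: simulate/ingest -> decompose -> fit -> transfer -> relate.

All stochasticity lives in the synthetic generator; downstream stages are
deterministic, so a run is fully reproducible (byte-identical CSV outputs)
given the configuration and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
import pandas as pd
import yaml

from . import synthetic
from .decomposition import PairEnergyCurve, build_pair_curves
from .fitting import BuckinghamFit, detect_pathology, fit_repulsive
from .iqa_io import (
    ScanRecord,
    default_ionization_table,
    read_ionization_table,
    read_scan_table,
    write_scan_table,
)
from .relations import fit_ab_relation
from .transfer import TransferMatrix, build_matrix, export_heatmap, summarize_matrix

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "validate_inputs", "run_pipeline"]

ENERGY_KINDS = ("deformation", "steric")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either ``scan_tables`` (paths to ingest) or ``simulate`` (number of
    synthetic molecules) must be set.  ``fit_ranges`` maps atom type to
    (r_lo, r_hi) in Angstrom; atom types not listed are fitted over the full
    scan.
    """

    out_dir: Path
    scan_tables: list[Path] = field(default_factory=list)
    energy_unit: str | None = None
    ionization_table: Path | None = None
    rounding_mode: str = "floor"
    fit_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    transfer_threshold: float = 4.0  # kJ/mol
    seed: int = 0
    simulate: int = 0  # number of synthetic molecules; 0 = ingest mode
    noise_sigma: float = 0.5
    ct_amplitude: float = 0.0
    dip_amplitude: float = 0.0
    write_heatmaps: bool = False

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        self.scan_tables = [Path(p) for p in self.scan_tables]
        if self.ionization_table is not None:
            self.ionization_table = Path(self.ionization_table)
        if self.transfer_threshold <= 0:
            raise ValueError("transfer_threshold must be > 0")
        if self.rounding_mode not in ("floor", "ceiling"):
            raise ValueError("rounding_mode must be 'floor' or 'ceiling'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "fit_ranges" in raw:
            raw["fit_ranges"] = {
                k: tuple(v) for k, v in raw["fit_ranges"].items()
            }
        return cls(**raw)


def validate_inputs(config: RunConfig) -> list[str]:
    """Check schemas, units and record invariants without modifying anything.

    Returns a list of human-readable failure messages (empty = valid).
    """
    failures: list[str] = []
    if config.ionization_table is not None and not config.ionization_table.exists():
        failures.append(f"ionization table not found: {config.ionization_table}")
    if not config.simulate and not config.scan_tables:
        failures.append("no input: set scan_tables or simulate > 0")
    for path in config.scan_tables:
        if not path.exists():
            failures.append(f"scan table not found: {path}")
            continue
        try:
            read_scan_table(path, unit=config.energy_unit)
        except Exception as exc:  # noqa: BLE001 - report, don't crash
            failures.append(f"{path}: {exc}")
    return failures


@dataclass
class PipelineResult:
    curves: list[PairEnergyCurve]
    fits: dict[tuple[str, str, str], BuckinghamFit]  # (molecule, atom_type, kind)
    matrices: dict[tuple[str, str], TransferMatrix]  # (atom_type, kind)
    summaries: pd.DataFrame
    relations: dict[tuple[str, str], dict]
    manifest: pd.DataFrame | None
    report: dict


def _fit_curve(
    curve: PairEnergyCurve, kind: str, fit_range: tuple[float, float] | None
) -> BuckinghamFit:
    """Fit one curve and stamp it with the pathology detector's verdict.

    The fit is attempted even for flagged curves (their steric counterpart is
    usually fine and the parameters remain informative); flagged fits are
    excluded from transfer matrices downstream.  When a fit range is
    configured for the atom type, the pathology check is restricted to the
    same window — narrowing the scan range is precisely how problematic
    short- or long-range regions are kept out of the analysis.
    """
    e = curve.energy(kind)
    r = curve.separations
    if fit_range is not None:
        mask = (r >= fit_range[0]) & (r <= fit_range[1])
        pathology = detect_pathology(r[mask], e[mask])
    else:
        pathology = detect_pathology(r, e)
    fit = fit_repulsive(curve.separations, e, energy_kind=kind, fit_range=fit_range)
    if fit.pathology == "none" and pathology != "none":
        fit = replace(fit, pathology=pathology)
    return fit


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full analysis and write all artifacts under ``config.out_dir``."""
    failures = validate_inputs(config)
    if failures:
        raise ValueError("invalid inputs:\n" + "\n".join(failures))
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)

    table = (
        read_ionization_table(config.ionization_table)
        if config.ionization_table is not None
        else default_ionization_table()
    )

    manifest: pd.DataFrame | None = None
    records: list[ScanRecord] = []
    if config.simulate:
        specs, manifest = synthetic.generate_suite(
            config.simulate,
            seed=config.seed,
            ct_amplitude=config.ct_amplitude,
            dip_amplitude=config.dip_amplitude,
            noise_sigma=config.noise_sigma,
        )
        scans_dir = out / "scans"
        scans_dir.mkdir(exist_ok=True)
        for spec in specs:
            recs = synthetic.generate_scan(spec, table)
            records.extend(recs)
            write_scan_table(recs, scans_dir / f"{spec.molecule_id}.csv")
        manifest.to_csv(out / "manifest.csv", index=False, float_format="%.12g")
    else:
        for path in config.scan_tables:
            records.extend(read_scan_table(path, unit=config.energy_unit))

    curves = build_pair_curves(records, table, rounding_mode=config.rounding_mode)
    curves_dir = out / "curves"
    curves_dir.mkdir(exist_ok=True)
    for c in curves:
        c.to_frame().to_csv(
            curves_dir / f"{c.molecule_id}_{c.atom_type}.csv",
            index=False,
            float_format="%.12g",
        )

    fits: dict[tuple[str, str, str], BuckinghamFit] = {}
    fit_rows = []
    for c in curves:
        fr = config.fit_ranges.get(c.atom_type)
        for kind in ENERGY_KINDS:
            fit = _fit_curve(c, kind, fr)
            fits[(c.molecule_id, c.atom_type, kind)] = fit
            fit_rows.append(
                {
                    "molecule": c.molecule_id,
                    "atom": c.atom_type,
                    "energy_kind": kind,
                    "A": fit.A,
                    "B": fit.B,
                    "rmse": fit.rmse,
                    "n_points": fit.n_points,
                    "r_lo": fit.fit_range[0],
                    "r_hi": fit.fit_range[1],
                    "pathology": fit.pathology,
                }
            )
    fits_df = pd.DataFrame(fit_rows).sort_values(
        ["atom", "energy_kind", "molecule"], ignore_index=True
    )
    fits_df.to_csv(out / "fits.csv", index=False, float_format="%.12g")

    atom_types = sorted({c.atom_type for c in curves})
    matrices: dict[tuple[str, str], TransferMatrix] = {}
    summary_rows = []
    for atom_type in atom_types:
        type_curves = {c.molecule_id: c for c in curves if c.atom_type == atom_type}
        for kind in ENERGY_KINDS:
            type_fits = {
                m: fits[(m, atom_type, kind)]
                for m in type_curves
                if (m, atom_type, kind) in fits
            }
            try:
                matrix = build_matrix(type_fits, type_curves, kind, atom_type)
            except ValueError as exc:
                log.warning("transfer matrix %s/%s skipped: %s", atom_type, kind, exc)
                continue
            matrices[(atom_type, kind)] = matrix
            export_heatmap(
                matrix,
                out / f"transfer_{atom_type}_{kind}.csv",
                (out / f"transfer_{atom_type}_{kind}.png") if config.write_heatmaps else None,
            )
            for include_diagonal in (False, True):
                s = summarize_matrix(
                    matrix, config.transfer_threshold, include_diagonal=include_diagonal
                )
                summary_rows.append(
                    {
                        "atom_type": atom_type,
                        "energy_kind": kind,
                        "convention": "all" if include_diagonal else "offdiag",
                        "average": s.average,
                        "minimum": s.minimum,
                        "maximum": s.maximum,
                        "pct_below_threshold": s.pct_below_threshold,
                        "n_entries": s.n_entries,
                        "n_molecules": matrix.n,
                        "n_excluded": len(matrix.excluded),
                    }
                )
    summaries = pd.DataFrame(summary_rows)
    if not summaries.empty:
        summaries.to_csv(out / "transfer_summaries.csv", index=False, float_format="%.12g")

    relations: dict[tuple[str, str], dict] = {}
    for atom_type in atom_types:
        for kind in ENERGY_KINDS:
            ab = [
                (f.A, f.B)
                for (m, at, k), f in fits.items()
                if at == atom_type and k == kind and f.pathology == "none"
            ]
            if len(ab) < 3:
                continue
            A_vals = [p[0] for p in ab]
            B_vals = [p[1] for p in ab]
            rel = fit_ab_relation(A_vals, B_vals, model="exponential")
            entry = {
                "exponential": {
                    "a": rel.a, "b": rel.b, "r_squared": rel.r_squared,
                    "sse": rel.sse, "n_points": rel.n_points,
                }
            }
            if len(ab) >= 5:
                pw = fit_ab_relation(A_vals, B_vals, model="piecewise")
                entry["piecewise"] = {
                    "a": pw.a, "b": pw.b, "d": pw.d, "breakpoint": pw.breakpoint,
                    "r_squared": pw.r_squared, "sse": pw.sse, "n_points": pw.n_points,
                }
            relations[(atom_type, kind)] = entry

    report = {
        "seed": config.seed,
        "rounding_mode": config.rounding_mode,
        "transfer_threshold_kj_per_mol": config.transfer_threshold,
        "n_molecules": len({c.molecule_id for c in curves}),
        "n_curves": len(curves),
        "n_fits": len(fits),
        "n_pathological_fits": sum(1 for f in fits.values() if f.pathology != "none"),
        "excluded": {
            f"{at}_{kind}": list(m.excluded) for (at, kind), m in matrices.items()
        },
        "relations": {f"{at}_{kind}": v for (at, kind), v in relations.items()},
        "conventions": {
            "energy_unit": "kJ/mol",
            "distance_unit": "Angstrom",
            "rmse": "sqrt(mean squared residual), no dof correction",
            "transfer_summary_default": "off-diagonal entries only",
            "equivalent_atoms": "lowest atom index selected",
        },
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    lines = [f"{k}: {v}" for k, v in report.items() if k not in ("relations", "excluded")]
    (out / "report.txt").write_text("\n".join(lines) + "\n")

    return PipelineResult(
        curves=curves,
        fits=fits,
        matrices=matrices,
        summaries=summaries,
        relations=relations,
        manifest=manifest,
        report=report,
    )
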