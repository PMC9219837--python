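"""Deterministic tabular/JSON writers and the matching readers.

TSV floats are formatted at six significant digits so repeated runs are
byte-identical; JSON keeps full precision and carries a hash of the run
configuration for provenance.  Every file written here round-trips through
the reader in this module.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .design import DeltaMap, RobustnessSurface, ScanResult
from .fba import FluxState, FVAResult

__all__ = [
    "config_hash",
    "write_flux_tsv",
    "read_flux_tsv",
    "write_fva_tsv",
    "write_scan",
    "write_surface",
    "write_delta_map",
    "write_strain_table",
    "write_json",
]


def _fmt(value) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "infeasible"
    return f"{value:.6g}"


def config_hash(config: dict) -> str:
    """Stable SHA-256 hash of a JSON-serializable configuration mapping."""
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def write_flux_tsv(state: FluxState, path) -> Path:
    """Write a flux state as a reaction/flux TSV in model reaction order."""
    path = Path(path)
    with open(path, "w") as handle:
        handle.write("reaction\tflux\n")
        for rxn_id, flux in state.fluxes.items():
            handle.write(f"{rxn_id}\t{_fmt(flux)}\n")
    return path


def read_flux_tsv(path) -> dict[str, float]:
    frame = pd.read_csv(path, sep="\t")
    return dict(zip(frame["reaction"], frame["flux"].astype(float)))


def write_fva_tsv(result: FVAResult, path) -> Path:
    path = Path(path)
    with open(path, "w") as handle:
        handle.write("reaction\tmin\tmax\n")
        for rxn_id, (lo, hi) in result.ranges.items():
            handle.write(f"{rxn_id}\t{_fmt(lo)}\t{_fmt(hi)}\n")
    return path


def write_scan(result: ScanResult, outdir, stem: str = "scan") -> list[Path]:
    """Write a multiplier scan: long-format deltas, matrix, product trace."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    long_path = outdir / f"{stem}_delta_long.tsv"
    with open(long_path, "w") as handle:
        handle.write("reaction\tmultiplier\tdelta_normalized\n")
        for rxn_id in result.delta_matrix.index:
            for k in result.spec.multipliers:
                handle.write(
                    f"{rxn_id}\t{_fmt(k)}\t{_fmt(result.delta_matrix.loc[rxn_id, k])}\n"
                )
    matrix_path = outdir / f"{stem}_delta_matrix.tsv"
    with open(matrix_path, "w") as handle:
        header = "\t".join(_fmt(k) for k in result.spec.multipliers)
        handle.write(f"reaction\t{header}\n")
        for rxn_id in result.delta_matrix.index:
            row = "\t".join(
                _fmt(result.delta_matrix.loc[rxn_id, k]) for k in result.spec.multipliers
            )
            handle.write(f"{rxn_id}\t{row}\n")
    trace_path = outdir / f"{stem}_product_trace.tsv"
    with open(trace_path, "w") as handle:
        handle.write("multiplier\tproduct_flux\n")
        for k in result.spec.multipliers:
            handle.write(f"{_fmt(k)}\t{_fmt(result.product_trace[k])}\n")
    return [long_path, matrix_path, trace_path]


def write_surface(surface: RobustnessSurface, path) -> Path:
    """Write a robustness surface in long format (growth, flux, product)."""
    path = Path(path)
    with open(path, "w") as handle:
        handle.write("growth\tconstrained_flux\tproduct_flux\n")
        for i, mu in enumerate(surface.growth_values):
            for j, f in enumerate(surface.flux_values):
                value = surface.objective_matrix[i, j] if surface.feasible_mask[i, j] else None
                handle.write(f"{_fmt(mu)}\t{_fmt(f)}\t{_fmt(value)}\n")
    return path


def write_delta_map(dmap: DeltaMap, path) -> Path:
    """Write a WT-vs-alternative comparison with its direction category."""
    path = Path(path)
    with open(path, "w") as handle:
        handle.write("reaction\twt_flux\talt_flux\tdelta_normalized\tdirection\n")
        for rxn_id, row in dmap.table.iterrows():
            handle.write(
                f"{rxn_id}\t{_fmt(row.wt_flux)}\t{_fmt(row.alt_flux)}\t"
                f"{_fmt(row.delta_normalized)}\t{row.direction}\n"
            )
    return path


def write_strain_table(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    with open(path, "w") as handle:
        handle.write("label\tgrowth_max\tproduct_flux\tstatus\n")
        for _, row in table.iterrows():
            handle.write(
                f"{row.label}\t{_fmt(row.growth_max)}\t{_fmt(row.product_flux)}\t"
                f"{row.status}\n"
            )
    return path


def write_json(payload: dict, path, config: dict | None = None) -> Path:
    """Write a JSON report; a config hash is embedded when config is given."""
    path = Path(path)
    body = dict(payload)
    if config is not None:
        body["config_hash"] = config_hash(config)
    with open(path, "w") as handle:
        json.dump(body, handle, indent=1, sort_keys=True, default=_json_default)
        handle.write("\n")
    return path


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
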