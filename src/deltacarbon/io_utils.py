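"""Output writing, manifests and provenance.

Every run is written as a self-describing NetCDF file (CF-style metadata),
flat CSV exports of the state, interface fluxes and budget ledger, the
fully resolved configuration, and a manifest with SHA-256 content hashes.
Deterministic runs produce identical hashes, and any output directory holds
everything needed to re-run its experiment.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .column_chain import RunOutput

__all__ = ["write_outputs", "sha256_file"]


def sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_outputs(run_output: RunOutput, out_dir: str | Path,
                  resolved_config_yaml: str | None = None) -> dict:
    """Write a run to ``out_dir`` and return the manifest.

    Emits ``state.nc`` (NetCDF), ``state.csv`` (one row per time x box x
    layer), ``fluxes.csv``, ``budget.csv``, ``config.yaml`` and
    ``manifest.json``; the manifest lists every emitted file with its
    SHA-256 hash.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not out.is_dir():
        raise NotADirectoryError(f"{out} is not a writable directory")

    ds = run_output.dataset
    nc_path = out / "state.nc"
    ds_enc = ds.copy()
    ds_enc.attrs["Conventions"] = "CF-1.8"
    ds_enc.attrs["closure_residual"] = run_output.closure
    ds_enc.to_netcdf(nc_path, engine="scipy")

    state_csv = out / "state.csv"
    ds.to_dataframe().reset_index().to_csv(state_csv, index=False)

    flux_csv = out / "fluxes.csv"
    run_output.fluxes.to_dataframe().reset_index().to_csv(flux_csv, index=False)

    budget_csv = out / "budget.csv"
    run_output.budget.to_frame().to_csv(budget_csv, index=False)

    config_path = out / "config.yaml"
    if resolved_config_yaml is None:
        resolved_config_yaml = json.dumps(run_output.config, sort_keys=True)
    config_path.write_text(resolved_config_yaml)

    files = [nc_path, state_csv, flux_csv, budget_csv, config_path]
    manifest = {
        "files": {p.name: sha256_file(p) for p in files},
        "closure_residual": run_output.closure,
        "spinup_days": run_output.spinup_days,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return manifest


def read_fluxes_csv(path: str | Path):
    """Round-trip a fluxes.csv back into the (time, interface, constituent)
    DataArray used by the flux-integration helpers."""
    import xarray as xr

    df = pd.read_csv(path, parse_dates=["time"])
    da = df.set_index(["time", "interface", "constituent"])[
        "interface_mass"].to_xarray()
    return da.rename("interface_mass")
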