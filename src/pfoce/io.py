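"""Container formats and configuration.

BM-mode volumes live in HDF5: one group per slow-axis position
(``position_0000``, ...) holding a complex ``field`` dataset with axes
(time, depth, fast), complex64 by default, little-endian, plus the
acquisition metadata as group attributes.  Bead records travel as CSV with
documented columns in SI units.  Run configuration is TOML.
"""

from __future__ import annotations

import warnings
from dataclasses import fields as dataclass_fields

import h5py
import numpy as np
import pandas as pd

from .beam import AcquisitionPlan, ForceProfile2D, LightSheetBeam
from .mechanics import BeadSpec, MediumSpec
from .pipeline import BeadRecord, BMStack

__all__ = [
    "write_bmstacks",
    "read_bmstacks",
    "write_force_profile",
    "read_force_profile",
    "write_bead_table",
    "read_bead_table",
    "load_config",
]

_STACK_ATTRS = (
    "frame_rate",
    "f_mod",
    "pixel_z",
    "pixel_x",
    "oct_wavelength",
    "medium_index",
    "drive_phase",
    "slow_position",
)

BEAD_TABLE_COLUMNS = [
    "id", "xc", "yc", "zc", "a_mech", "phi_mech",
    "F", "G_prime", "G_double_prime", "R", "qc",
]


def write_bmstacks(stacks: list[BMStack], path) -> None:
    """Write BM-mode stacks to an HDF5 container (one group per position)."""
    with h5py.File(path, "w") as h5:
        h5.attrs["format"] = "pfoce-bmstack-v1"
        for i, stack in enumerate(stacks):
            grp = h5.create_group(f"position_{i:04d}")
            data = stack.field
            if data.dtype == np.complex128:
                down = data.astype(np.complex64)
                err = np.max(np.abs(down - data))
                scale = np.max(np.abs(data)) or 1.0
                if err > 1e-6 * scale:
                    warnings.warn(
                        f"complex128 downcast loses {err / scale:.2e} relative precision"
                    )
                data = down
            grp.create_dataset("field", data=data)
            for name in _STACK_ATTRS:
                grp.attrs[name] = getattr(stack, name)


def read_bmstacks(path) -> list[BMStack]:
    """Read BM-mode stacks; raises on schema violations naming missing fields."""
    stacks = []
    with h5py.File(path, "r") as h5:
        names = sorted(k for k in h5.keys() if k.startswith("position_"))
        if not names:
            raise ValueError("no position groups found in container")
        for name in names:
            grp = h5[name]
            if "field" not in grp:
                raise ValueError(f"{name}: missing 'field' dataset")
            missing = [a for a in _STACK_ATTRS if a not in grp.attrs]
            if missing:
                raise ValueError(f"{name}: missing attributes {missing}")
            kwargs = {a: grp.attrs[a] for a in _STACK_ATTRS}
            stacks.append(BMStack(field=grp["field"][()], **kwargs))
    return stacks


def write_force_profile(profile: ForceProfile2D, path) -> None:
    """Force map as a long-format CSV (x, z, F) plus provenance comment."""
    xx, zz = np.meshgrid(profile.grid_x, profile.grid_z)
    df = pd.DataFrame(
        {"x": xx.ravel(), "z": zz.ravel(), "F": profile.force.ravel()}
    )
    with open(path, "w") as fh:
        fh.write(f"# provenance: {profile.provenance}\n")
        df.to_csv(fh, index=False)


def read_force_profile(path) -> ForceProfile2D:
    with open(path) as fh:
        first = fh.readline()
        provenance = "simulated"
        if first.startswith("#"):
            provenance = first.split(":", 1)[1].strip()
        else:
            fh.seek(0)
        df = pd.read_csv(fh)
    grid_x = np.unique(df["x"].to_numpy())
    grid_z = np.unique(df["z"].to_numpy())
    force = (
        df.pivot(index="z", columns="x", values="F")
        .reindex(index=grid_z, columns=grid_x)
        .to_numpy()
    )
    return ForceProfile2D(grid_x=grid_x, grid_z=grid_z, force=force, provenance=provenance)


def write_bead_table(records: list[BeadRecord], path) -> None:
    """Bead records as CSV.

    Columns (SI units): id, xc, yc, zc [m], a_mech [m], phi_mech [rad],
    F [N], G_prime [Pa], G_double_prime [Pa], R [-], qc (semicolon-joined
    flags).
    """
    rows = [
        {
            "id": r.bead_id, "xc": r.xc, "yc": r.yc, "zc": r.zc,
            "a_mech": r.a_mech, "phi_mech": r.phi_mech, "F": r.force,
            "G_prime": r.g_prime, "G_double_prime": r.g_double_prime,
            "R": r.loss_ratio, "qc": ";".join(r.qc_flags),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=BEAD_TABLE_COLUMNS).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_bead_table(path, check_loss_ratio: bool = True) -> list[BeadRecord]:
    """Read a bead table; malformed rows raise with their line number."""
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed bead table: {exc}") from exc
    missing = [c for c in BEAD_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"bead table missing columns {missing}")
    records = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            rec = BeadRecord(
                bead_id=int(row["id"]),
                xc=float(row["xc"]), yc=float(row["yc"]), zc=float(row["zc"]),
                a_mech=float(row["a_mech"]), phi_mech=float(row["phi_mech"]),
                n_voxels=0,
                force=float(row["F"]),
                g_prime=float(row["G_prime"]),
                g_double_prime=float(row["G_double_prime"]),
                loss_ratio=float(row["R"]),
                qc_flags=[] if pd.isna(row["qc"]) or row["qc"] == "" else str(row["qc"]).split(";"),
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed bead table row at line {line}: {exc}") from exc
        if (
            check_loss_ratio
            and np.isfinite(rec.g_prime)
            and rec.g_prime > 0
            and np.isfinite(rec.loss_ratio)
        ):
            expect = rec.g_double_prime / rec.g_prime
            if not np.isclose(rec.loss_ratio, expect, rtol=1e-9, atol=1e-12):
                raise ValueError(
                    f"inconsistent loss ratio at line {line}: "
                    f"R = {rec.loss_ratio} but G''/G' = {expect}"
                )
        records.append(rec)
    return records


_CONFIG_SECTIONS = {
    "beam": LightSheetBeam,
    "bead": BeadSpec,
    "medium": MediumSpec,
    "plan": AcquisitionPlan,
}


def load_config(path):
    """Load a TOML run configuration into typed parameter objects.

    Recognised sections: [beam], [bead], [medium], [plan]; top-level key
    ``seed``.  Unknown sections or keys are rejected so that typos surface
    instead of silently falling back to defaults.
    """
    import tomllib

    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    out = {}
    for key, value in raw.items():
        if key == "seed":
            out["seed"] = int(value)
            continue
        if key not in _CONFIG_SECTIONS:
            raise ValueError(f"unknown config section '{key}'")
        cls = _CONFIG_SECTIONS[key]
        allowed = {f.name for f in dataclass_fields(cls)}
        unknown = set(value) - allowed
        if unknown:
            raise ValueError(f"unknown keys in [{key}]: {sorted(unknown)}")
        if key == "medium" and "complex_shear_modulus" in value:
            pair = value.pop("complex_shear_modulus")
            value["complex_shear_modulus"] = complex(pair[0], pair[1])
        out[key] = cls(**value)
    return out
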