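"""Profile CSV round-tripping and run manifests.

Profiles are written with full ``repr`` precision so a write/read cycle is
bit-stable.  A run manifest records config hashes, seeds, package version
and output paths so a run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .transit import ProfileSet

PROFILE_COLUMNS = (
    "time_min",
    "dissolved_pct",
    "permeated_pct",
    "solid_pct",
    "sampled_pct",
    "pH",
    "volume_mL",
)


def write_profile(profile: ProfileSet, path: str | Path) -> Path:
    path = Path(path)
    profile.to_frame().to_csv(path, index=False, float_format="%.17g")
    return path


def read_profile(path: str | Path) -> ProfileSet:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(PROFILE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return ProfileSet(
        times=df["time_min"].to_numpy(float),
        dissolved_pct=df["dissolved_pct"].to_numpy(float),
        permeated_pct=df["permeated_pct"].to_numpy(float),
        solid_pct=df["solid_pct"].to_numpy(float),
        sampled_pct=df["sampled_pct"].to_numpy(float),
        donor_ph=df["pH"].to_numpy(float),
        donor_volume=df["volume_mL"].to_numpy(float),
    )


def read_measured_profile(path: str | Path) -> ProfileSet:
    """Read a bench-style table (time_min, dissolved_pct, permeated_pct).

    Missing device-state columns are filled with NaN so measured data can
    enter the similarity pipeline alongside simulated profiles.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("time_min", "permeated_pct"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    n = len(df)
    nan = np.full(n, np.nan)
    return ProfileSet(
        times=df["time_min"].to_numpy(float),
        dissolved_pct=df.get("dissolved_pct", pd.Series(nan)).to_numpy(float),
        permeated_pct=df["permeated_pct"].to_numpy(float),
        solid_pct=df.get("solid_pct", pd.Series(nan)).to_numpy(float),
        sampled_pct=df.get("sampled_pct", pd.Series(np.zeros(n))).to_numpy(float),
        donor_ph=df.get("pH", pd.Series(nan)).to_numpy(float),
        donor_volume=df.get("volume_mL", pd.Series(nan)).to_numpy(float),
    )


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(
    path: str | Path,
    config_paths: dict[str, str | Path],
    output_paths: list[str | Path],
    seed: int | None = None,
    extra: dict | None = None,
) -> Path:
    from . import __version__

    manifest = {
        "package_version": __version__,
        "seed": seed,
        "config_hashes": {
            name: file_sha256(p) for name, p in sorted(config_paths.items())
        },
        "outputs": [str(p) for p in output_paths],
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
    }
    if extra:
        manifest.update(extra)
    path = Path(path)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
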