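"""CSV dialects, model serialization and run configuration.

All tables are plain CSV with unit-suffixed column names:

* survival curves: ``dose_gy, surviving_fraction[, sf_sd]``
* alpha/beta records: ``alpha_per_gy, beta_per_gy2, let_kev_um, particle,
  cell_line``
* y_F tables: ``particle, energy_mev (optional), let_kev_um, radius_um,
  yf_kev_um``

Models round-trip through flat ``key = value`` text (keys ``z_f_gy``,
``mode``, ``s1 .. sK``); run configs are INI files with one section per
subcommand.
"""

from __future__ import annotations

import configparser
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import SurvivalModel
from .inference import AlphaBetaRecord, SurvivalCurve
from .microdosimetry import MicrodosimetryTable
from .repair import RepairScenario

__all__ = [
    "CsvFormatError",
    "read_survival_csv",
    "write_survival_csv",
    "read_alphabeta_csv",
    "write_alphabeta_csv",
    "read_yf_csv",
    "write_yf_csv",
    "read_model",
    "write_model",
    "load_config",
    "repair_scenario_from_config",
]

SURVIVAL_COLUMNS = ["dose_gy", "surviving_fraction"]
ALPHABETA_COLUMNS = ["alpha_per_gy", "beta_per_gy2", "let_kev_um"]
YF_COLUMNS = ["particle", "let_kev_um", "radius_um", "yf_kev_um"]


class CsvFormatError(ValueError):
    """Malformed CSV input; the message names the offending line."""


def _check_header(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CsvFormatError(f"{path}: missing column(s) {missing}")


def read_survival_csv(path) -> SurvivalCurve:
    """Read a survival curve; rows are sorted by dose, duplicates rejected."""
    path = Path(path)
    df = pd.read_csv(path)
    _check_header(df, SURVIVAL_COLUMNS, path)
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        sf = row["surviving_fraction"]
        if not np.isfinite(row["dose_gy"]) or row["dose_gy"] < 0:
            raise CsvFormatError(f"{path}:{line}: bad dose_gy {row['dose_gy']!r}")
        if not np.isfinite(sf) or sf <= 0 or sf > 1:
            raise CsvFormatError(
                f"{path}:{line}: surviving_fraction {sf!r} outside (0, 1]"
            )
    if df["dose_gy"].duplicated().any():
        dup = df.loc[df["dose_gy"].duplicated(), "dose_gy"].iloc[0]
        raise CsvFormatError(f"{path}: duplicate dose {dup} Gy")
    df = df.sort_values("dose_gy").reset_index(drop=True)
    sd = df["sf_sd"].to_numpy(float) if "sf_sd" in df.columns else None
    return SurvivalCurve(
        doses=df["dose_gy"].to_numpy(float),
        surviving_fraction=df["surviving_fraction"].to_numpy(float),
        sf_sd=sd,
        label=str(path.stem),
    )


def write_survival_csv(curve: SurvivalCurve, path) -> None:
    data = {
        "dose_gy": curve.doses,
        "surviving_fraction": curve.surviving_fraction,
    }
    if curve.sf_sd is not None:
        data["sf_sd"] = curve.sf_sd
    pd.DataFrame(data).to_csv(path, index=False)


def read_alphabeta_csv(path) -> list[AlphaBetaRecord]:
    """Read an (alpha, beta, LET) record table; negative beta rejected."""
    path = Path(path)
    df = pd.read_csv(path)
    _check_header(df, ALPHABETA_COLUMNS, path)
    records = []
    for i, row in df.iterrows():
        line = i + 2
        try:
            records.append(
                AlphaBetaRecord(
                    alpha=float(row["alpha_per_gy"]),
                    beta=float(row["beta_per_gy2"]),
                    let=float(row["let_kev_um"]),
                    particle="" if pd.isna(row.get("particle")) else str(row.get("particle")),
                    cell_line="" if pd.isna(row.get("cell_line")) else str(row.get("cell_line")),
                )
            )
        except (ValueError, TypeError) as exc:
            raise CsvFormatError(f"{path}:{line}: {exc}") from exc
    return records


def write_alphabeta_csv(records: Sequence[AlphaBetaRecord], path) -> None:
    pd.DataFrame(
        {
            "alpha_per_gy": [r.alpha for r in records],
            "beta_per_gy2": [r.beta for r in records],
            "let_kev_um": [r.let for r in records],
            "particle": [r.particle for r in records],
            "cell_line": [r.cell_line for r in records],
        }
    ).to_csv(path, index=False)


def read_yf_csv(path) -> MicrodosimetryTable:
    path = Path(path)
    df = pd.read_csv(path)
    _check_header(df, ["particle", "radius_um", "yf_kev_um"], path)
    return MicrodosimetryTable(data=df, provenance=str(path))


def write_yf_csv(table: MicrodosimetryTable, path) -> None:
    table.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# model serialization: flat key = value text


def write_model(model: SurvivalModel, path) -> None:
    lines = [f"z_f_gy = {model.z_f!r}", f"mode = {model.mode}"]
    lines += [f"s{k} = {v!r}" for k, v in enumerate(model.s, start=1)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_model(path) -> SurvivalModel:
    kv: dict[str, str] = {}
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        raw = raw.strip()
        if not raw or raw.startswith("#"):
            continue
        if "=" not in raw:
            raise CsvFormatError(f"{path}:{ln}: expected 'key = value'")
        key, _, value = raw.partition("=")
        kv[key.strip()] = value.strip()
    z_f = float(kv.pop("z_f_gy"))
    mode = kv.pop("mode", "truncated")
    s = []
    k = 1
    while f"s{k}" in kv:
        s.append(float(kv.pop(f"s{k}")))
        k += 1
    if kv:
        raise CsvFormatError(f"{path}: unknown keys {sorted(kv)}")
    return SurvivalModel(z_f=z_f, s=tuple(s), mode=mode)  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# run configuration


def load_config(path) -> configparser.ConfigParser:
    """INI run config with one section per subcommand."""
    cfg = configparser.ConfigParser()
    read = cfg.read(path)
    if not read:
        raise FileNotFoundError(path)
    return cfg


def repair_scenario_from_config(cfg: configparser.ConfigParser, section: str = "repair") -> RepairScenario:
    """Build a repair scenario from a ``[repair]`` config section.

    Keys: ``dose_rate_gy_s``, ``fraction_dose_gy``, ``z_f_gy``,
    ``repair_half_time_s``.
    """
    sec = cfg[section]
    return RepairScenario(
        dose_rate=sec.getfloat("dose_rate_gy_s"),
        fraction_dose=sec.getfloat("fraction_dose_gy"),
        z_f=sec.getfloat("z_f_gy"),
        repair_half_time=sec.getfloat("repair_half_time_s"),
    )
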