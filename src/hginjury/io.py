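"""Readers/writers for cohorts, count tables and reports.

Cohorts travel as CSV (``athlete_id,position,regime,f0..f{D-1},inj_<site>...``,
UTF-8, comma-separated, header mandatory) with a JSON sidecar
(``<path>.meta.json``) holding the interaction groups, the generating
configuration, its seed and a config hash so any stochastic output can be
re-derived exactly.  Writes are atomic (temp file + rename).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from hginjury.cohort import AthleteCohort, SimulationConfig
from hginjury.stats import MODES, InjuryCountTable


class SchemaError(ValueError):
    """A file does not match the documented schema."""


def atomic_write_text(path: str | Path, text: str) -> None:
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def config_hash(config: SimulationConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=list)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _cohort_frame(cohort: AthleteCohort) -> pd.DataFrame:
    d = cohort.features.shape[1]
    df = pd.DataFrame(
        {
            "athlete_id": cohort.athlete_id,
            "position": cohort.position,
            "regime": cohort.regime,
        }
    )
    feats = pd.DataFrame(cohort.features, columns=[f"f{i}" for i in range(d)])
    labels = pd.DataFrame(
        cohort.injury_labels, columns=[f"inj_{s}" for s in cohort.sites]
    )
    return pd.concat([df, feats, labels], axis=1)


def write_cohort(cohort: AthleteCohort, path: str | Path) -> None:
    path = Path(path)
    atomic_write_text(path, _cohort_frame(cohort).to_csv(index=False))
    meta = {
        "interaction_groups": [list(g) for g in cohort.interaction_groups],
        "sites": list(cohort.sites),
    }
    if cohort.config is not None:
        meta["config"] = dataclasses.asdict(cohort.config)
        meta["seed"] = cohort.config.seed
        meta["config_hash"] = config_hash(cohort.config)
    atomic_write_text(path.with_suffix(path.suffix + ".meta.json"), json.dumps(meta, indent=1))


def read_cohort(path: str | Path) -> AthleteCohort:
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("athlete_id", "position", "regime"):
        if col not in df.columns:
            raise SchemaError(f"cohort file missing required column {col!r}")
    feat_cols = [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]
    feat_cols.sort(key=lambda c: int(c[1:]))
    inj_cols = [c for c in df.columns if c.startswith("inj_")]
    if not feat_cols:
        raise SchemaError("cohort file has no feature columns f0..f{D-1}")
    if not inj_cols:
        raise SchemaError("cohort file has no injury label columns inj_*")
    labels = df[inj_cols].to_numpy()
    for c in inj_cols:
        if not np.isin(df[c].to_numpy(), (0, 1)).all():
            raise SchemaError(f"injury label column {c!r} contains non-binary values")
    bad_regime = set(df["regime"]) - set(MODES)
    if bad_regime:
        raise SchemaError(f"column 'regime' contains unknown values {sorted(bad_regime)}")

    meta_path = path.with_suffix(path.suffix + ".meta.json")
    groups: tuple = ()
    config = None
    sites = tuple(c[len("inj_") :] for c in inj_cols)
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        groups = tuple(tuple(g) for g in meta.get("interaction_groups", []))
        if "config" in meta:
            c = dict(meta["config"])
            c["group_size_range"] = tuple(c["group_size_range"])
            if c.get("site_rates") is not None:
                c["site_rates"] = tuple(tuple(r) for r in c["site_rates"])
            config = SimulationConfig(**c)
    return AthleteCohort(
        athlete_id=df["athlete_id"].to_numpy(),
        position=df["position"].to_numpy(dtype=object),
        regime=df["regime"].to_numpy(dtype=object),
        features=df[feat_cols].to_numpy(dtype=float),
        injury_labels=labels.astype(int),
        interaction_groups=groups,
        sites=sites,
        config=config,
    )


def write_count_table(t: InjuryCountTable, path: str | Path) -> None:
    df = pd.DataFrame(
        {"site": t.sites, "traditional": t.traditional, "maft": t.maft}
    )
    atomic_write_text(path, df.to_csv(index=False))


def read_count_table(path: str | Path, n_per_mode: int = 26) -> InjuryCountTable:
    df = pd.read_csv(path)
    for col in ("site", "traditional", "maft"):
        if col not in df.columns:
            raise SchemaError(f"count table missing required column {col!r}")
    return InjuryCountTable(
        sites=tuple(df["site"]),
        traditional=tuple(int(x) for x in df["traditional"]),
        maft=tuple(int(x) for x in df["maft"]),
        n_per_mode=n_per_mode,
    )
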