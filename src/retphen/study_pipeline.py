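"""Cohort orchestration: manifest -> per-animal tables -> group summaries.

Runs the three modality analyses over a cohort manifest and emits tidy
long-format tables at the reporting granularity of a typical study:
per-animal values (eyes/retinas pre-averaged) and per-group mean +- SEM
for every (genotype, age group, measure) cell.  Inferential statistics
(repeated-measures ANOVA, post hoc tests) are deliberately left to
standard statistical software; the emitted tables are designed for
direct consumption there.

Manifest CSV columns: ``animal_id, genotype, age_group, modality, path,
eye_or_retina`` with modality in {vessel, erg, oct}.  For vessels the
path is the dataset JSON; for ERG a directory of sweep CSVs; for OCT the
boundary JSON of one eye.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as _io
from .erg_waveform import ErgConfig, analyze_intensity_series
from .oct_thickness import animal_profile, thickness_profile
from .vessel_caliber import VesselConfig, measure_retina, summarize_mouse, summarize_retina

__all__ = ["load_manifest", "summarize_groups", "run_study"]

logger = logging.getLogger("retphen.study")

MANIFEST_COLUMNS = ("animal_id", "genotype", "age_group", "modality", "path", "eye_or_retina")


def load_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    if df[["animal_id", "genotype", "age_group"]].isna().any().any():
        raise ValueError("manifest has empty animal/genotype/age labels")
    dup = df.duplicated(subset=["animal_id", "modality", "eye_or_retina"])
    if dup.any():
        raise ValueError("duplicate (animal_id, modality, eye_or_retina) rows")
    return df


def summarize_groups(
    per_animal: pd.DataFrame,
    keys: tuple[str, ...] = ("genotype", "age_group", "measure"),
    value: str = "value",
) -> pd.DataFrame:
    """Mean +- SEM per group cell; SEM is absent (NaN) for n = 1.

    One row per animal feeds each cell (eyes/retinas must already be
    averaged).  Output rows are deterministically ordered by the keys.
    """
    if per_animal.empty:
        raise ValueError("empty per-animal table")

    def _cell(g: pd.DataFrame) -> pd.Series:
        vals = g[value].astype(float)
        n = int(vals.notna().sum())
        mean = float(vals.mean()) if n else np.nan
        sem = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        return pd.Series({"n": n, "mean": mean, "sem": sem})

    out = (
        per_animal.groupby(list(keys), sort=True)
        .apply(_cell, include_groups=False)
        .reset_index()
    )
    out["n"] = out["n"].astype(int)
    return out


# ---------------------------------------------------------------------------
# per-modality workers: manifest rows for one animal -> tidy measure rows
# ---------------------------------------------------------------------------


def _vessel_measures(rows: pd.DataFrame, base: Path, cfg: VesselConfig) -> pd.DataFrame:
    summaries = []
    for _, row in rows.iterrows():
        img, traces, circle = _io.read_vessel_dataset(base / row["path"])
        per_vessel = measure_retina(img, traces, circle, cfg)
        summaries.append(summarize_retina(per_vessel))
    mouse = summarize_mouse(summaries)
    recs = []
    for _, r in mouse.iterrows():
        recs.append({"measure": f"{r.vessel_class}_width_um", "value": r.mean_width_um})
        recs.append({"measure": f"{r.vessel_class}_count", "value": r.vessel_count})
    return pd.DataFrame(recs)


def _erg_measures(rows: pd.DataFrame, base: Path, cfg: ErgConfig) -> pd.DataFrame:
    # an ERG series belongs to one eye; multiple rows = multiple eyes, averaged
    per_eye = []
    for _, row in rows.iterrows():
        traces = _io.read_erg_directory(base / row["path"])
        features, fits = analyze_intensity_series(traces, cfg)
        recs = {
            "a_max_uv": features.a_amplitude_uv.max(),
            "b_max_uv": features.b_amplitude_uv.max(),
            "op_max_uv": features.op_magnitude_uv.max(),
        }
        nr = fits["naka_rushton"]
        if nr is not None:
            recs.update(vmax_uv=nr.vmax_uv, k_log=nr.k_log)
        lp = fits["lamb_pugh"]
        if lp is not None:
            recs.update(rmax_uv=lp.r_max_uv, tc_ms=lp.tc_ms, td_ms=lp.td_ms)
        per_eye.append(recs)
    df = pd.DataFrame(per_eye).mean(axis=0)
    return pd.DataFrame({"measure": df.index, "value": df.to_numpy()})


def _oct_measures(rows: pd.DataFrame, base: Path) -> pd.DataFrame:
    profiles = []
    for _, row in rows.iterrows():
        boundaries = _io.read_oct_boundaries(base / row["path"])
        profiles.append(thickness_profile(boundaries))
    prof = animal_profile(profiles)
    return pd.DataFrame(
        {
            "measure": [
                f"{r.layer}_at_{int(r.offset_um):+d}um" for r in prof.itertuples()
            ],
            "value": prof.thickness_um.to_numpy(),
        }
    )


# ---------------------------------------------------------------------------
# study runner
# ---------------------------------------------------------------------------


def run_study(
    manifest: pd.DataFrame | str | Path,
    out_dir: str | Path,
    config: dict | None = None,
    base_dir: str | Path | None = None,
) -> dict[str, pd.DataFrame]:
    """Run every modality over the cohort and write tidy output tables.

    Writes ``per_animal/<modality>.csv``, ``summaries/<modality>.csv``
    and ``run.log`` (with a full config echo) under ``out_dir``.  A row
    whose files are missing or unparseable is logged and skipped; the run
    continues.  Deterministic given inputs and config.

    Returns ``{"per_animal_<mod>": df, "summary_<mod>": df, ...}``.
    """
    if not isinstance(manifest, pd.DataFrame):
        manifest_path = Path(manifest)
        if base_dir is None:
            base_dir = manifest_path.parent
        manifest = load_manifest(manifest_path)
    base = Path(base_dir) if base_dir is not None else Path(".")
    out_dir = Path(out_dir)
    (out_dir / "per_animal").mkdir(parents=True, exist_ok=True)
    (out_dir / "summaries").mkdir(parents=True, exist_ok=True)

    config = config or {}
    vessel_cfg = VesselConfig(**config.get("vessel", {}))
    erg_cfg = ErgConfig(**config.get("erg", {}))

    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    logger.info("config echo:\n%s", yaml.safe_dump({"vessel": vessel_cfg.__dict__, "erg": erg_cfg.__dict__}))

    workers = {
        "vessel": lambda rows: _vessel_measures(rows, base, vessel_cfg),
        "erg": lambda rows: _erg_measures(rows, base, erg_cfg),
        "oct": lambda rows: _oct_measures(rows, base),
    }
    outputs: dict[str, pd.DataFrame] = {}
    try:
        for modality, worker in workers.items():
            sub = manifest[manifest.modality == modality]
            if sub.empty:
                continue
            animal_rows = []
            for (animal, genotype, age), rows in sub.groupby(
                ["animal_id", "genotype", "age_group"], sort=True
            ):
                try:
                    measures = worker(rows)
                except Exception as e:  # noqa: BLE001 - per-row errors recorded
                    logger.error("animal %s (%s): %s", animal, modality, e)
                    continue
                measures = measures.assign(
                    animal_id=animal, genotype=genotype, age_group=age
                )
                animal_rows.append(measures)
            if not animal_rows:
                logger.warning("no usable animals for modality %s", modality)
                continue
            per_animal = pd.concat(animal_rows, ignore_index=True)[
                ["animal_id", "genotype", "age_group", "measure", "value"]
            ].sort_values(["animal_id", "measure"], kind="stable", ignore_index=True)
            summary = summarize_groups(per_animal)
            per_animal.to_csv(out_dir / "per_animal" / f"{modality}.csv", index=False)
            summary.to_csv(out_dir / "summaries" / f"{modality}.csv", index=False)
            outputs[f"per_animal_{modality}"] = per_animal
            outputs[f"summary_{modality}"] = summary
            logger.info("modality %s: %d animals", modality, per_animal.animal_id.nunique())
    finally:
        logger.removeHandler(handler)
        handler.close()
    return outputs
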