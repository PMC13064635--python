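"""Readers and writers for the pipeline's artifacts.

Tabular artifacts (designs, choice tables, summaries) are tab-separated
text with documented headers; posterior draws go to an ``.npz`` container
with a JSON sidecar of settings and diagnostics; beta and statistic maps
are NIfTI volumes via nibabel.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .choice_model import VARIANTS
from .hierarchical import FitSettings, PosteriorFit
from .isrsa import BetaMaps

DESIGN_COLUMNS = ("trial_index", "c_one", "c_group", "n_group", "default_cond")
CHOICE_COLUMNS = DESIGN_COLUMNS + ("chose_one",)


class FormatError(ValueError):
    """Malformed or truncated artifact file."""


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def _read_tsv(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing artifact: {path}")
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as err:
        raise FormatError(f"cannot parse {path}: {err}") from err
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path} lacks required columns {missing}")
    if df[list(required)].isna().any().any():
        raise FormatError(f"{path} has missing values in required columns "
                          f"(truncated file?)")
    return df


def read_design(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, DESIGN_COLUMNS)


def read_choices(path: str | Path) -> pd.DataFrame:
    """Read a cohort (or single-subject) choice table."""
    df = _read_tsv(path, CHOICE_COLUMNS)
    if "subject" not in df.columns:
        df.insert(0, "subject", 0)
    return df


# ---------------------------------------------------------------------------
# posterior fits


def save_fit(fit: PosteriorFit, path: str | Path) -> Path:
    """Write draws to ``<path>.npz`` and settings/diagnostics to
    ``<path>.json``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {f"subject__{k}": v for k, v in fit.subject_draws.items()}
    arrays.update({f"group__{k}": v for k, v in fit.group_draws.items()})
    arrays["log_lik"] = fit.log_lik
    np.savez_compressed(path.with_suffix(".npz"), **arrays)
    sidecar = {
        "model": fit.model.name,
        "subjects": list(map(str, fit.subjects)),
        "diagnostics": fit.diagnostics,
        "settings": {
            "chains": fit.settings.chains,
            "warmup": fit.settings.warmup,
            "draws": fit.settings.draws,
            "seed": fit.settings.seed,
            "target_accept": fit.settings.target_accept,
            "parameterization": fit.settings.parameterization,
        },
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path.with_suffix(".npz")


def load_fit(path: str | Path) -> PosteriorFit:
    path = Path(path)
    npz_path, json_path = path.with_suffix(".npz"), path.with_suffix(".json")
    for p in (npz_path, json_path):
        if not p.exists():
            raise FileNotFoundError(f"missing artifact: {p}")
    sidecar = json.loads(json_path.read_text())
    with np.load(npz_path) as z:
        subject_draws = {
            k.split("__", 1)[1]: z[k] for k in z.files if k.startswith("subject__")
        }
        group_draws = {
            k.split("__", 1)[1]: z[k] for k in z.files if k.startswith("group__")
        }
        log_lik = z["log_lik"]
    st = sidecar["settings"]
    return PosteriorFit(
        model=VARIANTS[sidecar["model"]],
        subjects=sidecar["subjects"],
        subject_draws=subject_draws,
        group_draws=group_draws,
        log_lik=log_lik,
        diagnostics=sidecar["diagnostics"],
        settings=FitSettings(
            chains=st["chains"], warmup=st["warmup"], draws=st["draws"],
            seed=st["seed"], target_accept=st["target_accept"],
            parameterization=st["parameterization"],
        ),
    )


# ---------------------------------------------------------------------------
# NIfTI volumes


def save_beta_maps(maps: BetaMaps, path: str | Path) -> Path:
    """Write beta maps as a 4-D NIfTI (x, y, z, subject)."""
    import nibabel as nib

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    vols = np.stack(
        [maps.to_volume(maps.data[s], fill=0.0) for s in range(maps.n_subjects)],
        axis=-1,
    )
    nib.save(nib.Nifti1Image(vols.astype(np.float32), maps.affine), str(path))
    return path


def load_beta_maps(path: str | Path, mask: np.ndarray | None = None) -> BetaMaps:
    import nibabel as nib

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing artifact: {path}")
    img = nib.load(str(path))
    vols = np.asarray(img.dataobj, float)
    if vols.ndim != 4:
        raise FormatError(f"{path}: expected a 4-D (x,y,z,subject) image")
    shape = vols.shape[:3]
    flat = vols.reshape(-1, vols.shape[3]).T
    if mask is not None:
        flat = flat[:, np.asarray(mask, bool)]
    return BetaMaps(data=flat, shape=shape, mask=mask, affine=img.affine)


def save_volume(volume: np.ndarray, affine: np.ndarray, path: str | Path) -> Path:
    import nibabel as nib

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(volume, np.float32), affine), str(path))
    return path
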