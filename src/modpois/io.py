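"""CSV readers/writers and model-spec config handling.

Dialect: comma-separated, UTF-8, header row required.  Required columns
are ``Y`` and ``E`` (strictly 0/1) plus the covariates named by the
model spec; extra columns are ignored with a logged notice.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .model import ModelSpec, build_design
from .protocol import SiteData
from .simulate import site_to_frame

logger = logging.getLogger(__name__)


def read_model_spec(path) -> ModelSpec:
    """Load a ModelSpec from JSON: {"covariates": [...], "interactions": [...]}."""
    with open(path) as fh:
        doc = json.load(fh)
    if not isinstance(doc, dict) or "covariates" not in doc:
        raise ConfigurationError(f"{path}: spec JSON must contain a 'covariates' list")
    return ModelSpec(
        covariate_names=tuple(doc["covariates"]),
        interaction_terms=tuple(doc.get("interactions", ())),
    )


def infer_model_spec(path) -> ModelSpec:
    """Build a main-effects spec from a CSV header: everything but Y and E."""
    header = pd.read_csv(path, nrows=0).columns.tolist()
    covs = [c for c in header if c not in ("Y", "E")]
    if not covs:
        raise ConfigurationError(f"{path}: no covariate columns besides Y and E")
    return ModelSpec(covariate_names=tuple(covs))


def _binary_column(df: pd.DataFrame, col: str, path) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad_numeric = vals.isna()
    if bad_numeric.any():
        row = int(np.flatnonzero(bad_numeric.to_numpy())[0]) + 1
        raise ValidationError(
            f"{path}: column {col!r} has a non-numeric value at row {row}"
        )
    arr = vals.to_numpy(dtype=float)
    bad = ~np.isin(arr, (0.0, 1.0))
    if bad.any():
        row = int(np.flatnonzero(bad)[0]) + 1
        raise ValidationError(
            f"{path}: column {col!r} must be 0/1 but has value {arr[bad][0]!r} at row {row}"
        )
    return arr


def read_site_csv(path, spec: ModelSpec, site_id: Optional[str] = None) -> SiteData:
    """Read and validate one partner's CSV into a :class:`SiteData`.

    Row numbers in error messages are 1-based data rows (the header is
    row 0).
    """
    path = Path(path)
    try:
        # round_trip parsing: a write/read cycle preserves floats bit-exactly
        df = pd.read_csv(path, float_precision="round_trip")
    except FileNotFoundError:
        raise ValidationError(f"data file not found: {path}")
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: file is empty or has no header")

    missing = [c for c in ("Y", "E", *spec.covariate_names) if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    extras = [c for c in df.columns if c not in ("Y", "E", *spec.covariate_names)]
    if extras:
        logger.info("%s: ignoring extra columns %s", path, extras)
    if len(df) == 0:
        raise ValidationError(f"{path}: no data rows")

    y = _binary_column(df, "Y", path)
    E = _binary_column(df, "E", path)
    X = pd.DataFrame(index=df.index)
    for col in spec.covariate_names:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(np.flatnonzero(vals.isna().to_numpy())[0]) + 1
            raise ValidationError(
                f"{path}: column {col!r} has a non-numeric value at row {row}"
            )
        X[col] = vals.to_numpy(dtype=float)

    design = build_design(E, X, spec, y=y)
    logger.info("%s: read %d rows, %d regressors", path, design.n, design.p)
    return SiteData(site_id=site_id or path.stem, design=design)


def write_site_csv(site: SiteData, path, spec: Optional[ModelSpec] = None) -> Path:
    """Write a site's raw table (Y, E, covariates) as CSV."""
    path = Path(path)
    site_to_frame(site, spec).to_csv(path, index=False)
    return path


def read_beta_json(path) -> tuple[np.ndarray, int]:
    """Read a coefficient broadcast file; returns (beta, iteration)."""
    from .messages import BroadcastMessage, read_message

    msg = read_message(path)
    if not isinstance(msg, BroadcastMessage):
        raise ConfigurationError(f"{path}: expected a broadcast message")
    return msg.beta, msg.iteration
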