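"""Covariate encoding shared by the mixed-model screen and the mixture model.

Reference levels follow the trial convention: female sex, ECOG 0, standard
arm.  Age enters as a raw numeric column.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import ValidationError

_SEX_LEVELS = ("female", "male")
_ARM_LEVELS = ("standard", "experimental")


def build_covariate_design(
    covariates: pd.DataFrame, names: tuple[str, ...] | list[str]
) -> tuple[np.ndarray, list[str], dict[str, list[str]]]:
    """Encode named covariates into a design matrix (no intercept).

    Returns ``(X, column_names, blocks)`` where ``blocks`` maps each
    requested covariate to the design columns it produced (ECOG expands to
    two indicator columns against reference level 0).
    """
    cols: list[np.ndarray] = []
    colnames: list[str] = []
    blocks: dict[str, list[str]] = {}
    for name in names:
        if name not in covariates.columns:
            raise ValidationError(f"covariate {name!r} not present in the panel")
        s = covariates[name]
        if name == "sex":
            vals = s.astype(str).str.lower()
            bad = set(vals) - set(_SEX_LEVELS)
            if bad:
                raise ValidationError(f"unknown sex level(s) {sorted(bad)}")
            cols.append((vals == "male").to_numpy(float))
            colnames.append("sex[male]")
            blocks[name] = ["sex[male]"]
        elif name == "ecog":
            vals = pd.to_numeric(s, errors="raise").astype(int)
            bad = set(vals) - {0, 1, 2}
            if bad:
                raise ValidationError(f"unknown ECOG level(s) {sorted(bad)}")
            blocks[name] = []
            for lev in (1, 2):
                cols.append((vals == lev).to_numpy(float))
                colnames.append(f"ecog[{lev}]")
                blocks[name].append(f"ecog[{lev}]")
        elif name == "arm":
            vals = s.astype(str).str.lower()
            bad = set(vals) - set(_ARM_LEVELS)
            if bad:
                raise ValidationError(f"unknown arm level(s) {sorted(bad)}")
            cols.append((vals == "experimental").to_numpy(float))
            colnames.append("arm[experimental]")
            blocks[name] = ["arm[experimental]"]
        else:
            vals = pd.to_numeric(s, errors="raise").to_numpy(float)
            cols.append(vals)
            colnames.append(name)
            blocks[name] = [name]
    X = np.column_stack(cols) if cols else np.empty((len(covariates), 0))
    return X, colnames, blocks
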