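"""Longitudinal event-record dataset: a NONMEM-flavoured CSV dialect.

Columns
-------
ID      subject identifier
TIME    days since first dose (>= 0)
EVID    1 = dose event, 0 = observation
AMT     dose amount in mg (dose rows only)
TINF    infusion duration in days (dose rows only)
DV      observed value (mg/L for drug, ng/L for ligand)
DVID    1 = drug (bevacizumab), 2 = ligand (free VEGF-A)
MDV     1 = missing DV (dose rows), 0 = observed
PREDOSE 1 if the sample is a trough (pre-dose) draw, else 0

plus per-subject covariate columns (constant within subject):
WT (kg), AGE (years), SEX (1 male / 0 female), RS699947, RS1570360,
RS2010963, RS5498, RS1799969 (0 wild-type / 1 mutant carrier),
REG (1 = 5 mg/kg q2w, 2 = 7.5 mg/kg q3w), COTX (1 irinotecan / 0 oxaliplatin).

Concentrations are stored on the assay scale; molar conversion happens only
inside the binding model (see :mod:`bevpkpd.units`).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .units import DRUG, LIGAND

MANDATORY = ["ID", "TIME", "EVID", "AMT", "TINF", "DV", "DVID", "MDV"]
COVARIATE_COLUMNS = [
    "WT", "AGE", "SEX",
    "RS699947", "RS1570360", "RS2010963", "RS5498", "RS1799969",
    "REG", "COTX",
]
SNP_COLUMNS = ["RS699947", "RS1570360", "RS2010963", "RS5498", "RS1799969"]
DVID_TO_OBSERVABLE = {1: DRUG, 2: LIGAND}


class DatasetFormatError(ValueError):
    """A structural problem with the file (missing columns, bad dialect)."""


class DatasetValidationError(ValueError):
    """A row-level violation (negative time, non-positive dose, ...)."""


class Dataset:
    """Validated event-record table with per-subject covariates attached."""

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        self.df = _normalize(df)
        if validate:
            self.validate()

    # -- accessors ---------------------------------------------------------
    @property
    def subject_ids(self) -> np.ndarray:
        return self.df["ID"].unique()

    @property
    def n_subjects(self) -> int:
        return self.df["ID"].nunique()

    def doses(self) -> pd.DataFrame:
        return self.df[self.df["EVID"] == 1]

    def observations(self) -> pd.DataFrame:
        return self.df[self.df["EVID"] == 0]

    def covariates(self) -> pd.DataFrame:
        """One row per subject with the covariate columns."""
        cols = [c for c in COVARIATE_COLUMNS if c in self.df.columns]
        return self.df.groupby("ID", sort=False)[cols].first()

    def observation_counts(self) -> pd.DataFrame:
        obs = self.observations()
        return obs.groupby(["DVID", "PREDOSE"]).size().unstack(fill_value=0)

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        df = self.df
        missing = [c for c in MANDATORY if c not in df.columns]
        if missing:
            raise DatasetFormatError(f"missing mandatory column(s): {missing}")
        bad = df.index[df["TIME"] < 0]
        if len(bad):
            raise DatasetValidationError(f"negative TIME at row(s) {list(bad[:5])}")
        doses = df[df["EVID"] == 1]
        bad = doses.index[~(doses["AMT"] > 0)]
        if len(bad):
            raise DatasetValidationError(f"non-positive dose AMT at row(s) {list(bad[:5])}")
        bad = doses.index[~(doses["TINF"] > 0)]
        if len(bad):
            raise DatasetValidationError(f"non-positive infusion duration at row(s) {list(bad[:5])}")
        obs = df[(df["EVID"] == 0) & (df["MDV"] == 0)]
        bad = obs.index[~(obs["DV"] > 0)]
        if len(bad):
            raise DatasetValidationError(f"non-positive observation DV at row(s) {list(bad[:5])}")
        bad = obs.index[~obs["DVID"].isin(DVID_TO_OBSERVABLE)]
        if len(bad):
            raise DatasetValidationError(f"unknown DVID at row(s) {list(bad[:5])}")
        for col in [c for c in COVARIATE_COLUMNS if c in df.columns]:
            nun = df.groupby("ID")[col].nunique()
            varying = nun[nun > 1]
            if len(varying):
                raise DatasetValidationError(
                    f"covariate {col} varies within subject(s) {list(varying.index[:5])}"
                )

    # -- i/o ---------------------------------------------------------------
    def write(self, path: str | Path) -> None:
        cols = MANDATORY + ["PREDOSE"] + [c for c in COVARIATE_COLUMNS if c in self.df.columns]
        out = self.df[cols].copy()
        out.to_csv(path, index=False, float_format="%.10g")

    def __eq__(self, other) -> bool:  # row-content equality
        if not isinstance(other, Dataset):
            return NotImplemented
        a, b = self.df.reset_index(drop=True), other.df.reset_index(drop=True)
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        try:
            pd.testing.assert_frame_equal(a, b, check_dtype=False, atol=0, rtol=1e-12)
        except AssertionError:
            return False
        return True


def _normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Stable sort: subject order preserved, time ascending, dose before observation at ties."""
    df = df.copy()
    if "PREDOSE" not in df.columns:
        df["PREDOSE"] = 0
    # EVID descending at equal times puts dose (1) before observation (0)
    order = np.lexsort((-df["EVID"].to_numpy(), df["TIME"].to_numpy(),
                        pd.factorize(df["ID"])[0]))
    return df.iloc[order].reset_index(drop=True)


def read_dataset(path: str | Path, column_map: str | Path | dict | None = None) -> Dataset:
    """Read the CSV dialect; ``column_map`` (dict or YAML path) renames
    non-standard column headers onto the dialect's names."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if column_map is not None:
        if not isinstance(column_map, dict):
            with open(column_map) as fh:
                column_map = yaml.safe_load(fh)
        df = df.rename(columns=column_map)
    missing = [c for c in MANDATORY if c not in df.columns]
    if missing:
        raise DatasetFormatError(f"{path.name}: missing mandatory column(s): {missing}")
    return Dataset(df)


def write_dataset(dataset: Dataset, path: str | Path) -> None:
    dataset.write(path)
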