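"""Pedigree and longitudinal phenotype tables for the 2x-4x trial design.

The pedigree maps each breeding hybrid to its diploid (2x) and tetraploid
(4x) parent and full-sib family; phenotypes are long-format records, one row
per plant x crop cycle x trait (controls additionally carry a replicate
index because they are the only plants repeated within a block).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .traits import TRAIT_CATALOG

log = logging.getLogger("triploidcross.genotypes")

PEDIGREE_COLUMNS = ["hybrid_id", "parent2x_id", "parent4x_id", "family_id"]
PHENOTYPE_COLUMNS = [
    "plant_id", "type", "trial_id", "block_id", "cycle",
    "replicate", "trait", "value",
]


@dataclass
class StudyTables:
    """Validated pedigree + phenotype tables.

    ``pedigree``: one row per breeding hybrid with its (2x, 4x) parent pair.
    ``phenotypes``: long records; ``type`` is ``breed`` or ``control``;
    ``cycle`` is in {1, 2, 3}; ``block_id`` is nested in ``trial_id``.
    """

    pedigree: pd.DataFrame
    phenotypes: pd.DataFrame

    def __post_init__(self) -> None:
        ped = self.pedigree
        phe = self.phenotypes
        missing = [c for c in PEDIGREE_COLUMNS if c not in ped.columns]
        if missing:
            raise ValueError(f"pedigree is missing columns {missing}")
        missing = [c for c in PHENOTYPE_COLUMNS if c not in phe.columns]
        if missing:
            raise ValueError(f"phenotypes are missing columns {missing}")
        if ped["hybrid_id"].duplicated().any():
            dup = ped.loc[ped["hybrid_id"].duplicated(), "hybrid_id"].tolist()
            raise ValueError(f"hybrids with more than one parent pair: {dup}")
        bad = set(phe["cycle"].unique()) - {1, 2, 3}
        if bad:
            raise ValueError(f"cycle values outside {{1,2,3}}: {sorted(bad)}")
        bad_type = set(phe["type"].unique()) - {"breed", "control"}
        if bad_type:
            raise ValueError(f"unknown plant types: {sorted(bad_type)}")
        key = ["plant_id", "cycle", "replicate", "trait"]
        if phe.duplicated(subset=key).any():
            dup = phe.loc[phe.duplicated(subset=key), key].head()
            raise ValueError(f"duplicate (plant, cycle, replicate) records:\n{dup}")
        breed_rep = phe.loc[(phe["type"] == "breed") & (phe["replicate"] > 1)]
        if len(breed_rep):
            raise ValueError(
                "replicate index > 1 found for breed plants: only controls "
                "are repeated within a block"
            )
        nest = phe.groupby("block_id")["trial_id"].nunique()
        if (nest > 1).any():
            raise ValueError(
                f"blocks spanning several trials: {nest[nest > 1].index.tolist()}"
            )

    # -- convenience views -------------------------------------------------

    @property
    def traits(self) -> list[str]:
        return sorted(self.phenotypes["trait"].unique())

    @property
    def crosses(self) -> pd.DataFrame:
        """One row per (2x, 4x) parent combination with progeny count."""
        g = self.pedigree.groupby(["parent2x_id", "parent4x_id"], sort=True)
        out = g.size().rename("n_progeny").reset_index()
        return out

    @property
    def n_families(self) -> int:
        return self.pedigree["family_id"].nunique()

    def trait_observations(self, trait: str) -> pd.DataFrame:
        """Observation rows for one trait, pedigree columns merged in.

        Controls get ``parent2x_id``/``parent4x_id`` of NA, and a
        ``genotype_id`` column identifying the repeated control variety
        (for breed hybrids ``genotype_id`` equals ``hybrid_id``).
        """
        phe = self.phenotypes[self.phenotypes["trait"] == trait].copy()
        if phe.empty:
            raise KeyError(f"no phenotype records for trait {trait!r}")
        phe = phe.merge(
            self.pedigree, how="left", left_on="plant_id", right_on="hybrid_id"
        )
        is_control = phe["type"] == "control"
        phe["genotype_id"] = phe["plant_id"].where(~is_control, phe["plant_id"])
        if "control_variety" in self.phenotypes.columns:
            phe["genotype_id"] = phe["genotype_id"].where(
                ~is_control, phe["control_variety"]
            )
        # a physical plant = (plant_id, replicate); controls are re-planted
        phe["unit_id"] = (
            phe["plant_id"].astype(str)
            + "|" + phe["block_id"].astype(str)
            + "|r" + phe["replicate"].astype(str)
        )
        phe.loc[~is_control, "unit_id"] = phe.loc[~is_control, "plant_id"].astype(str)
        return phe


def load_study_tables(
    pedigree_path: str,
    phenotype_path: str,
    column_map: dict[str, str] | None = None,
    sep: str = ",",
) -> StudyTables:
    """Load delimited pedigree/phenotype files into validated tables.

    ``column_map`` renames file columns onto the canonical names
    (``{"file column": "canonical name"}``).  Rows whose parents are unknown
    (absent from the pedigree) are retained but flagged in the log.
    """
    ped = pd.read_csv(pedigree_path, sep=sep)
    phe = pd.read_csv(phenotype_path, sep=sep)
    if column_map:
        ped = ped.rename(columns=column_map)
        phe = phe.rename(columns=column_map)
    if "replicate" not in phe.columns:
        phe["replicate"] = 1
    tables = StudyTables(pedigree=ped, phenotypes=phe)

    known = set(ped["hybrid_id"])
    breed = phe.loc[phe["type"] == "breed", "plant_id"]
    orphans = sorted(set(breed) - known)
    if orphans:
        log.warning("%d breed plants without pedigree rows (kept, flagged): %s",
                    len(orphans), orphans[:10])
    per_trait = phe.groupby("trait").size()
    log.info("loaded %d phenotype rows over %d traits; %d pedigree rows, "
             "%d families", len(phe), len(per_trait), len(ped),
             tables.n_families)
    return tables


__all__ = [
    "StudyTables", "load_study_tables", "TRAIT_CATALOG",
    "PEDIGREE_COLUMNS", "PHENOTYPE_COLUMNS",
]
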