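"""Destrieux cortical parcellation table and region groupings.

The package ships a fixed table of the 148 cortical regions of the
Destrieux atlas (74 gyral/sulcal parcels per hemisphere), keyed by the
FreeSurfer ``aparc.a2009s`` label strings with an ``lh_``/``rh_`` prefix
(e.g. ``lh_S_temporal_sup``).  Thickness matrices from other tools are
matched against these names through a tolerant alias map (dots vs
underscores, ``&`` vs ``and``, optional ``_thickness`` suffix).

The temporal-lobe roster (15 regions per hemisphere, 30 in total) is part
of the packaged table, not code: it comprises every a2009s label whose
name contains ``temp`` — the superior/middle/inferior temporal gyri and
sulci, the transverse temporal gyrus and sulcus, planum polare and planum
temporale, the temporal pole, and the occipito-temporal (fusiform,
lingual, parahippocampal) labels.  This is an assumption: the atlas
defines the parcels, but the assignment of border parcels to "temporal"
is a convention, recorded here as reviewable data.
"""

from __future__ import annotations

import re
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

N_REGIONS = 148
N_PER_HEMISPHERE = 74
N_TEMPORAL = 30
N_EXTRATEMPORAL = 118

#: canonical names of the left and right superior temporal sulcus
STS_LEFT = "lh_S_temporal_sup"
STS_RIGHT = "rh_S_temporal_sup"

_ATLAS_RESOURCE = "destrieux_a2009s.tsv"


class AtlasError(RuntimeError):
    """Raised when the packaged atlas table is missing or corrupt."""


def _read_packaged_table() -> pd.DataFrame:
    try:
        ref = resources.files("normdev.data").joinpath(_ATLAS_RESOURCE)
        with ref.open("r") as fh:
            return pd.read_csv(fh, sep="\t")
    except (FileNotFoundError, OSError) as exc:  # pragma: no cover
        raise AtlasError(f"packaged atlas table {_ATLAS_RESOURCE!r} unavailable: {exc}")


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    expected_cols = ["region_id", "name", "hemisphere", "kind", "lobe_group"]
    if list(table.columns) != expected_cols:
        raise AtlasError(f"atlas columns {list(table.columns)} != {expected_cols}")
    if len(table) != N_REGIONS:
        raise AtlasError(f"atlas has {len(table)} rows, expected {N_REGIONS}")
    if not (table["region_id"].to_numpy() == np.arange(N_REGIONS)).all():
        raise AtlasError("region_id must run 0..147 in order")
    if table["name"].duplicated().any():
        raise AtlasError("duplicate region names")
    hemi_counts = table["hemisphere"].value_counts()
    if dict(hemi_counts) != {"left": N_PER_HEMISPHERE, "right": N_PER_HEMISPHERE}:
        raise AtlasError(f"hemisphere counts {dict(hemi_counts)}")
    lobe_counts = table["lobe_group"].value_counts()
    if dict(lobe_counts) != {"extratemporal": N_EXTRATEMPORAL, "temporal": N_TEMPORAL}:
        raise AtlasError(f"lobe_group counts {dict(lobe_counts)}")
    left = {n[3:] for n in table.loc[table.hemisphere == "left", "name"]}
    right = {n[3:] for n in table.loc[table.hemisphere == "right", "name"]}
    if left != right:
        raise AtlasError("left/right labels are not mirror pairs")
    if not set(table["kind"]) <= {"gyral", "sulcal"}:
        raise AtlasError("kind must be gyral or sulcal")
    for sts in (STS_LEFT, STS_RIGHT):
        row = table.loc[table.name == sts]
        if len(row) != 1 or row["lobe_group"].iloc[0] != "temporal":
            raise AtlasError(f"{sts} missing or not temporal")
    return table


def load_atlas() -> pd.DataFrame:
    """Load the packaged 148-region table.

    Returns a DataFrame with columns ``region_id`` (0..147), ``name``,
    ``hemisphere`` ({left, right}), ``kind`` ({gyral, sulcal}) and
    ``lobe_group`` ({temporal, extratemporal}), validated against the
    structural invariants of the parcellation (148 regions, 74 per
    hemisphere, 30 temporal / 118 extratemporal, mirror-paired names).
    """
    return _validate(_read_packaged_table())


def region_mask(
    table: pd.DataFrame,
    *,
    hemisphere: str | None = None,
    lobe_group: str | None = None,
    names: Iterable[str] | None = None,
) -> np.ndarray:
    """Boolean mask of length 148 selecting regions.

    Criteria combine with AND; ``names`` selects the listed regions
    (canonical or aliased spellings).  With no criteria the mask is
    all-True; ``names=[]`` yields an all-False mask.
    """
    mask = np.ones(len(table), dtype=bool)
    if hemisphere is not None:
        if hemisphere not in ("left", "right"):
            raise ValueError(f"hemisphere must be 'left' or 'right', got {hemisphere!r}")
        mask &= (table["hemisphere"] == hemisphere).to_numpy()
    if lobe_group is not None:
        if lobe_group not in ("temporal", "extratemporal"):
            raise ValueError(
                f"lobe_group must be 'temporal' or 'extratemporal', got {lobe_group!r}"
            )
        mask &= (table["lobe_group"] == lobe_group).to_numpy()
    if names is not None:
        keyed = {_alias_key(n): i for i, n in enumerate(table["name"])}
        sel = np.zeros(len(table), dtype=bool)
        missing = []
        for n in names:
            idx = keyed.get(_alias_key(n))
            if idx is None:
                missing.append(n)
            else:
                sel[idx] = True
        if missing:
            raise KeyError(f"unknown region name(s): {missing}")
        mask &= sel
    return mask


def _alias_key(name: str) -> str:
    """Canonicalisation key tolerant of common label dialects."""
    s = name.strip().lower().replace("&", "and")
    s = re.sub(r"thickness$", "", s)
    return re.sub(r"[._\-]", "", s)


def resolve_region_columns(columns: Sequence[str], table: pd.DataFrame | None = None) -> list[str]:
    """Map arbitrary column labels onto atlas order.

    Returns the input column labels reordered to match ``table`` row
    order (region_id 0..147).  Raises ``KeyError`` listing every atlas
    region with no matching column and every column matching no region.
    """
    if table is None:
        table = load_atlas()
    by_key: dict[str, str] = {}
    unmatched_cols = []
    atlas_keys = {_alias_key(n): n for n in table["name"]}
    for c in columns:
        k = _alias_key(str(c))
        if k in atlas_keys:
            if k in by_key:
                raise KeyError(f"column {c!r} duplicates region {atlas_keys[k]!r}")
            by_key[k] = c
        else:
            unmatched_cols.append(c)
    missing = [n for n in table["name"] if _alias_key(n) not in by_key]
    if missing or unmatched_cols:
        raise KeyError(
            "thickness columns do not match the atlas; "
            f"missing regions: {missing[:8]}{'...' if len(missing) > 8 else ''} "
            f"({len(missing)} total); unmatched columns: "
            f"{unmatched_cols[:8]}{'...' if len(unmatched_cols) > 8 else ''} "
            f"({len(unmatched_cols)} total)"
        )
    return [by_key[_alias_key(n)] for n in table["name"]]
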