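"""Core data containers shared by every pipeline stage.

The containers are thin, validated wrappers around pandas objects: an
intensity matrix with probe annotations (:class:`ExpressionMatrix`), a
per-sample design table (:class:`DesignTable`), a named gene-set collection
(:class:`GeneSetCollection`) and a long-format qPCR threshold-cycle table
(:class:`CtTable`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

#: Annotation columns with reserved meaning in expression TSV files.
RESERVED_ANNOTATION_COLUMNS = ("negative_control", "target")


def _duplicates(index: pd.Index) -> list:
    counts = index.value_counts()
    return list(counts.index[counts > 1])


@dataclass
class ExpressionMatrix:
    """A probes x samples intensity (or log2) matrix with probe annotations.

    Parameters
    ----------
    values
        DataFrame indexed by unique probe identifiers, one column per sample.
        Raw intensities must be non-negative; set ``log_scale=True`` for
        matrices already on the log2 scale (e.g. normalized log-ratios),
        where negative values are meaningful.
    annotations
        Optional DataFrame aligned to ``values.index``. The columns
        ``negative_control`` (bool) and ``target`` (probe -> target mapping)
        are recognised by downstream stages.
    log_scale
        Whether ``values`` holds log2 quantities.
    channel
        Optional channel tag (e.g. ``"red"``/``"green"`` for two-color data).
    """

    values: pd.DataFrame
    annotations: pd.DataFrame | None = None
    log_scale: bool = False
    channel: str | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        dups = _duplicates(self.values.index)
        if dups:
            raise ValueError(f"duplicate probe identifiers: {dups[:10]}")
        self.values = self.values.astype(float)
        if not self.log_scale:
            with np.errstate(invalid="ignore"):
                if (self.values.to_numpy() < 0).any():
                    raise ValueError("raw intensities must be non-negative")
        if self.annotations is not None:
            missing = self.values.index.difference(self.annotations.index)
            if len(missing):
                raise ValueError(
                    f"annotations missing for probes: {list(missing[:10])}"
                )
            self.annotations = self.annotations.loc[self.values.index]

    # -- convenience accessors -------------------------------------------
    @property
    def probes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def negative_control_mask(self) -> pd.Series:
        """Boolean mask of negative-control probes (False when unannotated)."""
        if self.annotations is None or "negative_control" not in self.annotations:
            return pd.Series(False, index=self.probes)
        return self.annotations["negative_control"].fillna(False).astype(bool)

    def target_map(self) -> pd.Series:
        """Probe -> target mapping; identity where no target is annotated."""
        ident = pd.Series(self.probes.to_numpy(), index=self.probes, dtype=object)
        if self.annotations is None or "target" not in self.annotations:
            return ident
        tgt = self.annotations["target"].astype(object)
        return tgt.where(tgt.notna(), ident)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(),
            None if self.annotations is None else self.annotations.copy(),
            self.log_scale,
            self.channel,
        )


@dataclass
class DesignTable:
    """Per-sample metadata: treatment group plus optional array/dye/include."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.table, pd.DataFrame):
            self.table = pd.DataFrame(self.table)
        for col in ("sample", "group"):
            if col not in self.table.columns:
                raise ValueError(f"design table requires a '{col}' column")
        self.table = self.table.reset_index(drop=True)
        self.table["sample"] = self.table["sample"].astype(str)
        self.table["group"] = self.table["group"].astype(str)
        dups = _duplicates(pd.Index(self.table["sample"]))
        if dups:
            raise ValueError(f"duplicate sample identifiers: {dups}")
        if "include" not in self.table.columns:
            self.table["include"] = True
        self.table["include"] = self.table["include"].astype(bool)

    @property
    def samples(self) -> list[str]:
        return list(self.table.loc[self.table["include"], "sample"])

    def group_of(self) -> pd.Series:
        sub = self.table[self.table["include"]]
        return pd.Series(sub["group"].to_numpy(), index=sub["sample"].to_numpy())

    def group_levels(self) -> list[str]:
        """Group levels with 'control' (if present) first, else sorted."""
        levels = sorted(set(self.table.loc[self.table["include"], "group"]))
        if "control" in levels:
            levels.remove("control")
            levels.insert(0, "control")
        return levels

    def samples_of(self, group: str) -> list[str]:
        sub = self.table[self.table["include"] & (self.table["group"] == group)]
        return list(sub["sample"])

    def two_group_masks(
        self,
        columns: Sequence[str],
        control: str | None = None,
        treated: str | None = None,
    ) -> tuple[np.ndarray, np.ndarray, tuple[str, str]]:
        """Boolean masks over ``columns`` for (control, treated) samples.

        Every included design sample must appear in ``columns``; levels
        default to :meth:`group_levels` order. Requires >= 2 samples in each
        group among ``columns``.
        """
        levels = self.group_levels()
        if control is None or treated is None:
            if len(levels) != 2:
                raise ValueError(
                    f"expected exactly two treatment groups, found {levels}"
                )
            control = control or levels[0]
            treated = treated or [l for l in levels if l != control][0]
        grp = self.group_of()
        missing = [s for s in grp.index if s not in set(columns)]
        if missing:
            raise ValueError(f"design samples absent from matrix: {missing}")
        cols = pd.Index(columns)
        in_design = cols.isin(grp.index)
        mask_c = in_design & (grp.reindex(cols).to_numpy() == control)
        mask_t = in_design & (grp.reindex(cols).to_numpy() == treated)
        if mask_c.sum() < 2 or mask_t.sum() < 2:
            raise ValueError("each treatment group needs >= 2 samples")
        return np.asarray(mask_c), np.asarray(mask_t), (control, treated)


class GeneSetCollection:
    """Named gene sets (GMT-style): unique names, ordered unique members."""

    def __init__(
        self,
        sets: Mapping[str, Sequence[str]],
        descriptions: Mapping[str, str] | None = None,
    ) -> None:
        self._sets: dict[str, tuple[str, ...]] = {}
        self.descriptions: dict[str, str] = {}
        for name, members in sets.items():
            uniq = list(dict.fromkeys(members))
            if len(uniq) < len(list(members)):
                warnings.warn(f"gene set '{name}' had duplicate members; deduplicated")
            if not uniq:
                raise ValueError(f"gene set '{name}' is empty")
            self._sets[str(name)] = tuple(uniq)
            self.descriptions[str(name)] = (
                "" if descriptions is None else str(descriptions.get(name, ""))
            )

    @property
    def names(self) -> list[str]:
        return list(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self) -> Iterator[str]:
        return iter(self._sets)

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __getitem__(self, name: str) -> tuple[str, ...]:
        return self._sets[name]

    def restrict(self, genes: Sequence[str]) -> "GeneSetCollection":
        """Intersect every set with ``genes``; drop (with warning) empty sets."""
        universe = set(genes)
        kept: dict[str, tuple[str, ...]] = {}
        for name, members in self._sets.items():
            inter = tuple(g for g in members if g in universe)
            if inter:
                kept[name] = inter
            else:
                warnings.warn(f"gene set '{name}' has no measured members; dropped")
        return GeneSetCollection(kept, self.descriptions)


@dataclass
class CtTable:
    """Long-format qPCR threshold-cycle table.

    ``wells`` columns: ``sample``, ``group``, ``gene``, ``ct`` and optionally
    ``replicate`` (technical replicate index). Technical replicates of a well
    are averaged before any analysis. ``efficiency`` is the per-cycle
    amplification efficiency, a scalar default or a per-gene mapping.
    """

    wells: pd.DataFrame
    housekeeping: tuple[str, ...] = ()
    efficiency: float | Mapping[str, float] = 2.0

    def __post_init__(self) -> None:
        required = {"sample", "group", "gene", "ct"}
        missing = required - set(self.wells.columns)
        if missing:
            raise ValueError(f"Ct table missing columns: {sorted(missing)}")
        self.wells = self.wells.copy()
        self.wells["ct"] = self.wells["ct"].astype(float)
        if (self.wells["ct"] <= 0).any():
            raise ValueError("Ct values must be > 0 cycles")
        self.housekeeping = tuple(self.housekeeping)
        if not self.housekeeping:
            raise ValueError("at least one housekeeping gene is required")
        genes = set(self.wells["gene"])
        absent = [g for g in self.housekeeping if g not in genes]
        if absent:
            raise ValueError(f"housekeeping genes not in table: {absent}")

    def efficiency_for(self, gene: str) -> float:
        if isinstance(self.efficiency, Mapping):
            return float(self.efficiency.get(gene, 2.0))
        return float(self.efficiency)

    def mean_ct(self) -> pd.DataFrame:
        """Samples x genes matrix of technical-replicate-averaged Ct values."""
        return self.wells.pivot_table(
            index="sample", columns="gene", values="ct", aggfunc="mean"
        )

    def sample_groups(self) -> pd.Series:
        grp = self.wells.drop_duplicates("sample").set_index("sample")["group"]
        return grp.astype(str)
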