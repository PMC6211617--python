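"""Shared data containers for the sliced-embryo ASE pipeline.

The pipeline revolves around three tabular objects:

``AlleleCountMatrix``
    Per-embryo, per-slice read counts assigned to each parental allele
    (*D. melanogaster* = ``mel``, *D. simulans* = ``sim``) for every gene.

``ASEMatrix``
    Genes x slices matrix of allele-specific expression scores in [-1, 1],
    with explicit missing entries, plus the anterior-posterior position of
    every slice as a fraction of egg length.

``NucleusAtlas``
    A point cloud of blastoderm nuclei (x, y, z in micrometres) with one
    expression column per gene or transcription factor; one atlas per
    species.

All containers read and write plain-text TSV/CSV so that every intermediate
is inspectable and diffable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

SPECIES = ("mel", "sim")
SEXES = ("male", "female")

_SAMPLE_RE = re.compile(r"^(?P<embryo>.+)_sl(?P<slice>\d+)$")
_COUNT_COL_RE = re.compile(r"^(?P<embryo>.+)_sl(?P<slice>\d+)_(?P<allele>mel|sim)$")


@dataclass(frozen=True)
class EmbryoSpec:
    """Metadata for a single cryo-sliced embryo.

    Slicing at 14 um resolution along the ~420 um anterior-posterior axis
    yields 25-27 slices per embryo; slice 1 is the anterior-most.
    """

    embryo_id: str
    mother: str = "mel"
    sex: str = "female"
    n_slices: int = 26
    length_um: float = 420.0
    slice_width_um: float = 14.0

    def __post_init__(self) -> None:
        if self.mother not in SPECIES:
            raise ValueError(f"mother must be one of {SPECIES}, got {self.mother!r}")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.n_slices < 2:
            raise ValueError("an embryo must have at least 2 slices")
        if self.length_um <= 0 or self.slice_width_um <= 0:
            raise ValueError("length_um and slice_width_um must be positive")
        if self.n_slices * self.slice_width_um > self.length_um + self.slice_width_um:
            raise ValueError(
                f"{self.n_slices} slices of {self.slice_width_um} um do not fit an "
                f"embryo of {self.length_um} um"
            )

    def slice_positions(self) -> np.ndarray:
        """Midpoint of each slice as a fraction of egg length (anterior = 0)."""
        i = np.arange(1, self.n_slices + 1)
        return (i - 0.5) / self.n_slices

    def sample_ids(self) -> list[str]:
        return [f"{self.embryo_id}_sl{i}" for i in range(1, self.n_slices + 1)]


def _embryo_lookup(embryos: Sequence[EmbryoSpec]) -> dict[str, EmbryoSpec]:
    lut = {e.embryo_id: e for e in embryos}
    if len(lut) != len(embryos):
        raise ValueError("duplicate embryo_id in embryo list")
    return lut


@dataclass
class AlleleCountMatrix:
    """Genes x (embryo, slice, allele) table of allele-assigned read counts.

    ``counts`` has the genes on the index and a three-level column
    MultiIndex ``(embryo, slice, allele)`` with allele in {"mel", "sim"}.
    Entries are non-negative; NaN marks counts masked by QC.
    """

    counts: pd.DataFrame
    embryos: list[EmbryoSpec]
    gene_chromosome: pd.Series | None = None  # 'autosome' or 'X' per gene

    def __post_init__(self) -> None:
        if not isinstance(self.counts.columns, pd.MultiIndex) or self.counts.columns.nlevels != 3:
            raise ValueError("counts must have a (embryo, slice, allele) column MultiIndex")
        vals = self.counts.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("read counts must be non-negative")
        lut = _embryo_lookup(self.embryos)
        for emb, sl, _ in self.counts.columns:
            if emb not in lut:
                raise ValueError(f"column embryo {emb!r} missing from embryo metadata")
            if not 1 <= sl <= lut[emb].n_slices:
                raise ValueError(f"slice {sl} out of range for embryo {emb!r}")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    def embryo(self, embryo_id: str) -> EmbryoSpec:
        return _embryo_lookup(self.embryos)[embryo_id]

    def sample_ids(self) -> list[str]:
        seen: list[str] = []
        for emb, sl in self.counts.columns.droplevel("allele").unique():
            seen.append(f"{emb}_sl{sl}")
        return seen

    def allele_counts(self, allele: str) -> pd.DataFrame:
        """Genes x (embryo, slice) counts for one allele."""
        sub = self.counts.xs(allele, axis=1, level="allele")
        return sub

    def write_tsv(self, counts_path: str | Path, embryos_path: str | Path) -> None:
        flat = self.counts.copy()
        flat.columns = [f"{e}_sl{s}_{a}" for e, s, a in flat.columns]
        flat.index.name = "gene"
        if self.gene_chromosome is not None:
            flat.insert(0, "chromosome", self.gene_chromosome.reindex(flat.index))
        flat.to_csv(counts_path, sep="\t", na_rep="NA")
        meta = pd.DataFrame(
            [
                {
                    "embryo_id": e.embryo_id,
                    "mother": e.mother,
                    "sex": e.sex,
                    "n_slices": e.n_slices,
                    "length_um": e.length_um,
                    "slice_width_um": e.slice_width_um,
                }
                for e in self.embryos
            ]
        )
        meta.to_csv(embryos_path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, counts_path: str | Path, embryos_path: str | Path) -> "AlleleCountMatrix":
        flat = pd.read_csv(counts_path, sep="\t", index_col="gene", na_values="NA")
        chrom = None
        if "chromosome" in flat.columns:
            chrom = flat.pop("chromosome")
        cols = []
        for c in flat.columns:
            m = _COUNT_COL_RE.match(c)
            if m is None:
                raise ValueError(f"unparseable count column {c!r}")
            cols.append((m["embryo"], int(m["slice"]), m["allele"]))
        flat.columns = pd.MultiIndex.from_tuples(cols, names=["embryo", "slice", "allele"])
        meta = pd.read_csv(embryos_path, sep="\t")
        embryos = [
            EmbryoSpec(
                embryo_id=str(r.embryo_id),
                mother=r.mother,
                sex=r.sex,
                n_slices=int(r.n_slices),
                length_um=float(r.length_um),
                slice_width_um=float(r.slice_width_um),
            )
            for r in meta.itertuples()
        ]
        return cls(counts=flat, embryos=embryos, gene_chromosome=chrom)


@dataclass
class ASEMatrix:
    """Genes x slices ASE scores with slice positions on the AP axis.

    ``values`` carries the scores (NaN = not callable) with a two-level
    ``(embryo, slice)`` column MultiIndex; ``x`` gives each column's slice
    midpoint as a fraction of egg length, normalized per embryo to [0, 1].
    """

    values: pd.DataFrame
    x: pd.Series
    embryos: list[EmbryoSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        vals = self.values.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < -1 - 1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("ASE values must lie in [-1, 1]")
        if not self.x.index.equals(self.values.columns):
            raise ValueError("x must be indexed by the value columns")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def gene_profile(self, gene: str) -> tuple[np.ndarray, np.ndarray]:
        """Pooled (x, ase) arrays for one gene with missing entries dropped."""
        y = self.values.loc[gene].to_numpy(dtype=float)
        x = self.x.to_numpy(dtype=float)
        keep = np.isfinite(y)
        return x[keep], y[keep]

    def write_tsv(self, path: str | Path) -> None:
        flat = self.values.copy()
        flat.columns = [f"{e}_sl{s}" for e, s in flat.columns]
        flat.index.name = "gene"
        out = pd.concat(
            [pd.DataFrame([self.x.to_numpy()], index=["__x__"], columns=flat.columns), flat]
        )
        out.index.name = "gene"
        out.to_csv(path, sep="\t", na_rep="NA")

    @classmethod
    def read_tsv(cls, path: str | Path, embryos: Sequence[EmbryoSpec] = ()) -> "ASEMatrix":
        flat = pd.read_csv(path, sep="\t", index_col="gene", na_values="NA")
        x_row = flat.loc["__x__"]
        flat = flat.drop(index="__x__")
        cols = []
        for c in flat.columns:
            m = _SAMPLE_RE.match(c)
            if m is None:
                raise ValueError(f"unparseable ASE column {c!r}")
            cols.append((m["embryo"], int(m["slice"])))
        mi = pd.MultiIndex.from_tuples(cols, names=["embryo", "slice"])
        flat.columns = mi
        x = pd.Series(x_row.to_numpy(dtype=float), index=mi)
        return cls(values=flat.astype(float), x=x, embryos=list(embryos))


@dataclass
class NucleusAtlas:
    """Point cloud of nuclei with per-gene expression; one atlas per species.

    ``data`` is indexed by nucleus id with columns ``x``, ``y``, ``z``
    (micrometres) followed by one column per gene or TF.
    """

    species: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        for c in ("x", "y", "z"):
            if c not in self.data.columns:
                raise ValueError(f"atlas is missing coordinate column {c!r}")
        coords = self.data[["x", "y", "z"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(coords)):
            raise ValueError("atlas coordinates must be finite")

    @property
    def gene_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("x", "y", "z")]

    def positions(self) -> np.ndarray:
        return self.data[["x", "y", "z"]].to_numpy(dtype=float)

    def x_fraction(self) -> pd.Series:
        """AP position of each nucleus as a fraction of this atlas's egg length."""
        x = self.data["x"].astype(float)
        span = x.max() - x.min()
        if span <= 0:
            raise ValueError("atlas has zero extent along x")
        return (x - x.min()) / span

    def write_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.index.name = "nucleus_id"
        out.to_csv(path)

    @classmethod
    def read_csv(cls, path: str | Path, species: str) -> "NucleusAtlas":
        data = pd.read_csv(path, index_col="nucleus_id")
        return cls(species=species, data=data)
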