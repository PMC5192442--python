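"""Embedded relational store for spectra, tags, and feature records.

Six relational tables: Spectrum (sample metadata), Tag (free-form
labels such as "fish" or "steamed"), SpectrumTag (classification
links), Bin (the per-solvent grid, stored once), BSpectrum (raw binned
intensities, one row per bin), and Feature (tasting and hardness
records; several records may point at one spectrum, e.g. one per panel
volunteer).

Raw intensities are stored; preprocessing happens at query time with
the query's own mask, and preprocessed matrices are cached per
(solvent, mask, method) until the next write.
"""

from __future__ import annotations

import enum
import math
import os
import sqlite3
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import GRIDS, Solvent, grid_for
from .preprocess import NormalizationError, RegionMask, preprocess
from .spectrum_io import BinnedSpectrum, read_spectrum

__all__ = [
    "FeatureKind",
    "SpectrumRecord",
    "FeatureRecord",
    "FoodDB",
    "import_dataset",
]

_SCHEMA = """
CREATE TABLE IF NOT EXISTS Spectrum (
    id       INTEGER PRIMARY KEY,
    name     TEXT NOT NULL UNIQUE,
    solvent  TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS Tag (
    id     INTEGER PRIMARY KEY,
    label  TEXT NOT NULL UNIQUE
);
CREATE TABLE IF NOT EXISTS SpectrumTag (
    spectrum_id INTEGER NOT NULL REFERENCES Spectrum(id) ON DELETE CASCADE,
    tag_id      INTEGER NOT NULL REFERENCES Tag(id) ON DELETE CASCADE,
    PRIMARY KEY (spectrum_id, tag_id)
);
CREATE TABLE IF NOT EXISTS Bin (
    solvent    TEXT NOT NULL,
    bin_index  INTEGER NOT NULL,
    center_ppm REAL NOT NULL,
    PRIMARY KEY (solvent, bin_index)
);
CREATE TABLE IF NOT EXISTS BSpectrum (
    spectrum_id INTEGER NOT NULL REFERENCES Spectrum(id) ON DELETE CASCADE,
    bin_index   INTEGER NOT NULL,
    intensity   REAL NOT NULL,
    PRIMARY KEY (spectrum_id, bin_index)
);
CREATE TABLE IF NOT EXISTS Feature (
    id          INTEGER PRIMARY KEY,
    spectrum_id INTEGER NOT NULL REFERENCES Spectrum(id) ON DELETE CASCADE,
    kind        TEXT NOT NULL CHECK (kind IN ('tasting', 'hardness')),
    value       REAL NOT NULL
);
"""


class FeatureKind(str, enum.Enum):
    TASTING = "tasting"
    HARDNESS = "hardness"

    @classmethod
    def parse(cls, text: "str | FeatureKind") -> "FeatureKind":
        if isinstance(text, FeatureKind):
            return text
        return cls(str(text).strip().lower())


@dataclass(frozen=True)
class SpectrumRecord:
    id: int
    name: str
    solvent: Solvent


@dataclass(frozen=True)
class FeatureRecord:
    id: int
    spectrum_id: int
    kind: FeatureKind
    value: float


class DuplicateNameError(ValueError):
    """A spectrum with this name is already registered."""


class FoodDB:
    """SQLite-backed spectrum/feature store."""

    def __init__(self, path: "str | os.PathLike" = ":memory:"):
        self.path = os.fspath(path)
        self._conn = sqlite3.connect(self.path)
        self._conn.execute("PRAGMA foreign_keys = ON")
        self._conn.executescript(_SCHEMA)
        self._materialize_bins()
        self._conn.commit()
        self._mutations = 0
        self._pp_cache: dict[tuple, tuple[list[int], np.ndarray]] = {}

    # -- lifecycle ---------------------------------------------------------

    def close(self) -> None:
        self._conn.close()

    def __enter__(self) -> "FoodDB":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    def _materialize_bins(self) -> None:
        cur = self._conn.execute("SELECT COUNT(*) FROM Bin")
        if cur.fetchone()[0]:
            return
        for solvent, grid in GRIDS.items():
            self._conn.executemany(
                "INSERT INTO Bin (solvent, bin_index, center_ppm) VALUES (?, ?, ?)",
                [(solvent.value, i, float(c)) for i, c in enumerate(grid.centers)],
            )

    def _dirty(self) -> None:
        self._mutations += 1
        self._pp_cache.clear()

    # -- spectra -----------------------------------------------------------

    def add_spectrum(
        self,
        spectrum: BinnedSpectrum,
        tags: "list[str] | tuple[str, ...]" = (),
        if_exists: str = "error",
    ) -> SpectrumRecord:
        """Persist a raw spectrum with its classification tags.

        ``if_exists`` controls duplicate names: ``'error'`` (default)
        raises, ``'skip'`` returns the existing record unchanged.
        """
        if spectrum.normalized:
            raise ValueError("store raw spectra; preprocessing happens at query time")
        if not spectrum.name:
            raise ValueError("spectrum must have a name to be registered")
        existing = self._conn.execute(
            "SELECT id, solvent FROM Spectrum WHERE name = ?", (spectrum.name,)
        ).fetchone()
        if existing is not None:
            if if_exists == "skip":
                return SpectrumRecord(existing[0], spectrum.name, Solvent(existing[1]))
            raise DuplicateNameError(f"spectrum named {spectrum.name!r} already exists")

        cur = self._conn.execute(
            "INSERT INTO Spectrum (name, solvent) VALUES (?, ?)",
            (spectrum.name, spectrum.grid.solvent.value),
        )
        sid = cur.lastrowid
        self._conn.executemany(
            "INSERT INTO BSpectrum (spectrum_id, bin_index, intensity) VALUES (?, ?, ?)",
            [(sid, i, float(v)) for i, v in enumerate(spectrum.intensities)],
        )
        all_tags = list(dict.fromkeys(list(spectrum.tags) + list(tags)))
        for label in all_tags:
            self._conn.execute("INSERT OR IGNORE INTO Tag (label) VALUES (?)", (label,))
            tag_id = self._conn.execute(
                "SELECT id FROM Tag WHERE label = ?", (label,)
            ).fetchone()[0]
            self._conn.execute(
                "INSERT INTO SpectrumTag (spectrum_id, tag_id) VALUES (?, ?)",
                (sid, tag_id),
            )
        self._conn.commit()
        self._dirty()
        return SpectrumRecord(sid, spectrum.name, spectrum.grid.solvent)

    def get_spectrum(self, spectrum_id: int) -> BinnedSpectrum:
        """Raw stored spectrum (bit-identical to what was inserted)."""
        row = self._conn.execute(
            "SELECT name, solvent FROM Spectrum WHERE id = ?", (spectrum_id,)
        ).fetchone()
        if row is None:
            raise KeyError(f"no spectrum with id {spectrum_id}")
        name, solvent = row
        grid = grid_for(solvent)
        data = self._conn.execute(
            "SELECT bin_index, intensity FROM BSpectrum WHERE spectrum_id = ? "
            "ORDER BY bin_index",
            (spectrum_id,),
        ).fetchall()
        v = np.zeros(grid.n_bins)
        for i, value in data:
            v[i] = value
        return BinnedSpectrum(
            grid=grid, intensities=v, name=name, tags=self.tags_of(spectrum_id)
        )

    def id_of(self, name: str) -> int:
        row = self._conn.execute(
            "SELECT id FROM Spectrum WHERE name = ?", (name,)
        ).fetchone()
        if row is None:
            raise KeyError(f"no spectrum named {name!r}")
        return row[0]

    def spectrum_ids(self, solvent: "str | Solvent | None" = None) -> list[int]:
        if solvent is None:
            rows = self._conn.execute("SELECT id FROM Spectrum ORDER BY id").fetchall()
        else:
            rows = self._conn.execute(
                "SELECT id FROM Spectrum WHERE solvent = ? ORDER BY id",
                (Solvent.parse(solvent).value,),
            ).fetchall()
        return [r[0] for r in rows]

    def names_of(self, spectrum_ids: "list[int]") -> dict[int, str]:
        out = {}
        for sid in spectrum_ids:
            row = self._conn.execute(
                "SELECT name FROM Spectrum WHERE id = ?", (sid,)
            ).fetchone()
            if row:
                out[sid] = row[0]
        return out

    def delete_spectrum(self, spectrum_id: int) -> None:
        """Remove a spectrum; links and features cascade."""
        self._conn.execute("DELETE FROM Spectrum WHERE id = ?", (spectrum_id,))
        self._conn.commit()
        self._dirty()

    def n_spectra(self, solvent: "str | Solvent | None" = None) -> int:
        return len(self.spectrum_ids(solvent))

    # -- tags --------------------------------------------------------------

    def tags_of(self, spectrum_id: int) -> list[str]:
        rows = self._conn.execute(
            "SELECT Tag.label FROM Tag JOIN SpectrumTag ON Tag.id = SpectrumTag.tag_id "
            "WHERE SpectrumTag.spectrum_id = ? ORDER BY Tag.id",
            (spectrum_id,),
        ).fetchall()
        return [r[0] for r in rows]

    def tag_labels(self) -> list[str]:
        return [r[0] for r in self._conn.execute("SELECT label FROM Tag ORDER BY id")]

    def ids_with_tag(self, label: str) -> list[int]:
        rows = self._conn.execute(
            "SELECT SpectrumTag.spectrum_id FROM SpectrumTag JOIN Tag "
            "ON Tag.id = SpectrumTag.tag_id WHERE Tag.label = ? "
            "ORDER BY SpectrumTag.spectrum_id",
            (label,),
        ).fetchall()
        return [r[0] for r in rows]

    def counts(self) -> dict[str, int]:
        out = {}
        for table in ("Spectrum", "Tag", "SpectrumTag", "Feature", "BSpectrum"):
            out[table] = self._conn.execute(
                f"SELECT COUNT(*) FROM {table}"
            ).fetchone()[0]
        return out

    # -- features ----------------------------------------------------------

    def add_feature(
        self, spectrum_id: int, kind: "str | FeatureKind", value: float
    ) -> FeatureRecord:
        """Append one tasting (integer 1-5) or hardness (positive real)."""
        kind = FeatureKind.parse(kind)
        value = float(value)
        if kind is FeatureKind.TASTING:
            if not (value.is_integer() and 1 <= value <= 5):
                raise ValueError(
                    f"tasting must be an integer in [1, 5], got {value}"
                )
        else:
            if not (math.isfinite(value) and value > 0):
                raise ValueError(f"hardness must be a positive real, got {value}")
        exists = self._conn.execute(
            "SELECT 1 FROM Spectrum WHERE id = ?", (spectrum_id,)
        ).fetchone()
        if exists is None:
            raise KeyError(f"no spectrum with id {spectrum_id}")
        cur = self._conn.execute(
            "INSERT INTO Feature (spectrum_id, kind, value) VALUES (?, ?, ?)",
            (spectrum_id, kind.value, value),
        )
        self._conn.commit()
        self._mutations += 1  # features do not affect the spectrum cache
        return FeatureRecord(cur.lastrowid, spectrum_id, kind, value)

    def features_of(
        self, spectrum_ids: "list[int]", kind: "str | FeatureKind"
    ) -> list[FeatureRecord]:
        """All feature records of one kind for the given spectra, by id."""
        kind = FeatureKind.parse(kind)
        if not spectrum_ids:
            return []
        placeholders = ",".join("?" for _ in spectrum_ids)
        rows = self._conn.execute(
            f"SELECT id, spectrum_id, value FROM Feature "
            f"WHERE kind = ? AND spectrum_id IN ({placeholders}) ORDER BY id",
            [kind.value, *spectrum_ids],
        ).fetchall()
        return [FeatureRecord(r[0], r[1], kind, r[2]) for r in rows]

    # -- preprocessed matrices ----------------------------------------------

    def preprocessed_matrix(
        self,
        solvent: "str | Solvent",
        mask: "RegionMask | None" = None,
        method: str = "sum_squares",
    ) -> tuple[list[int], np.ndarray]:
        """(ids, matrix) of preprocessed spectra for one partition.

        Spectra that are all-zero after filtering/masking cannot be
        normalized and are skipped with a warning.  Cached until the
        next database write.
        """
        solvent = Solvent.parse(solvent)
        mask_key = mask.key if mask else ()
        cache_key = (solvent, mask_key, method, self._mutations)
        if cache_key in self._pp_cache:
            return self._pp_cache[cache_key]

        ids, vectors = [], []
        for sid in self.spectrum_ids(solvent):
            raw = self.get_spectrum(sid)
            try:
                pp = preprocess(raw, mask=mask, method=method)
            except NormalizationError:
                warnings.warn(
                    f"spectrum {raw.name!r} (id {sid}) is all-zero after "
                    "preprocessing; excluded from comparisons",
                    stacklevel=2,
                )
                continue
            ids.append(sid)
            vectors.append(pp.intensities)
        matrix = (
            np.vstack(vectors)
            if vectors
            else np.empty((0, grid_for(solvent).n_bins))
        )
        self._pp_cache[cache_key] = (ids, matrix)
        return ids, matrix


def import_dataset(
    db: FoodDB,
    directory: "str | os.PathLike",
    manifest: "str | os.PathLike",
    features: "str | os.PathLike | None" = None,
) -> dict[str, int]:
    """Bulk-load spectrum files plus TSV manifest and feature files.

    The manifest has columns ``name``, ``solvent``, ``tags``
    (comma-separated, may be empty) and optionally ``file`` (defaults
    to ``<name>.tsv`` in *directory*).  The feature file has columns
    ``name``, ``kind``, ``value``.
    """
    directory = Path(directory)
    man = pd.read_csv(manifest, sep="\t", dtype=str, keep_default_na=False)
    n_spectra = 0
    for row in man.itertuples(index=False):
        fname = getattr(row, "file", "") or f"{row.name}.tsv"
        spectrum = read_spectrum(directory / fname, row.solvent)
        spectrum.name = row.name
        tags = [t for t in str(row.tags).replace(";", ",").split(",") if t.strip()]
        db.add_spectrum(spectrum, tags=[t.strip() for t in tags])
        n_spectra += 1

    n_features = 0
    if features is not None:
        feat = pd.read_csv(features, sep="\t", dtype={"name": str, "kind": str})
        for row in feat.itertuples(index=False):
            db.add_feature(db.id_of(row.name), row.kind, float(row.value))
            n_features += 1
    return {"spectra": n_spectra, "features": n_features}
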