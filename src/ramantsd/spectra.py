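"""Domain containers and plain-text IO for Raman spectra.

A spectrum is a single wavenumber/intensity trace with acquisition
metadata (donor, hour post-deposition, map spot).  A dataset bundles all
spectra of an aging experiment on one shared wavenumber grid and exposes
a spectra-by-channels matrix view for chemometrics.

Spectra are stored as two-column delimited text (comma or whitespace,
autodetected, optional header); an experiment manifest is JSON lines
with fields ``path``/``donor_id``/``hour``/``spot_index``, paths
relative to the manifest's directory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SpectrumMeta",
    "RamanSpectrum",
    "SpectraDataset",
    "ExperimentManifest",
    "default_grid",
    "read_spectrum",
    "write_spectrum",
    "read_manifest",
    "write_manifest",
    "read_dataset",
    "write_dataset",
    "harmonize",
]


def default_grid(low: float = 300.0, high: float = 1800.0, step: float = 1.0) -> np.ndarray:
    """Default collection grid: 300-1800 cm^-1 at 1 cm^-1 spacing."""
    n = int(round((high - low) / step)) + 1
    return low + step * np.arange(n)


@dataclass
class SpectrumMeta:
    donor_id: str = ""
    hour: float = 0.0
    spot_index: int = 0
    flags: set = field(default_factory=set)

    def copy(self) -> "SpectrumMeta":
        return SpectrumMeta(self.donor_id, self.hour, self.spot_index, set(self.flags))


class RamanSpectrum:
    """One wavenumber/intensity trace plus acquisition metadata.

    Parameters
    ----------
    wavenumbers : array-like
        Raman shifts in cm^-1, strictly increasing.
    intensities : array-like
        Intensities in arbitrary counts, same length.  Baseline-corrected
        spectra may carry negative values; raw spectra are nonnegative.
    meta : SpectrumMeta, optional
    """

    def __init__(self, wavenumbers, intensities, meta: SpectrumMeta | None = None):
        wn = np.asarray(wavenumbers, dtype=float)
        it = np.asarray(intensities, dtype=float)
        if wn.ndim != 1 or it.ndim != 1 or wn.size != it.size:
            raise ValueError("wavenumbers and intensities must be 1-D of equal length")
        if wn.size < 2:
            raise ValueError("a spectrum needs at least 2 channels")
        d = np.diff(wn)
        if np.any(d == 0):
            raise ValueError("duplicated wavenumbers in axis")
        if np.any(d < 0):
            raise ValueError("wavenumber axis must be strictly increasing")
        if not np.all(np.isfinite(wn)) or not np.all(np.isfinite(it)):
            raise ValueError("non-finite values in spectrum")
        self.wavenumbers = wn
        self.intensities = it
        self.meta = meta if meta is not None else SpectrumMeta()

    def __len__(self) -> int:
        return self.wavenumbers.size

    def __repr__(self) -> str:
        m = self.meta
        return (
            f"RamanSpectrum(n={len(self)}, "
            f"range=({self.wavenumbers[0]:g}, {self.wavenumbers[-1]:g}) cm-1, "
            f"donor={m.donor_id!r}, hour={m.hour:g}, spot={m.spot_index})"
        )

    def copy(self) -> "RamanSpectrum":
        return RamanSpectrum(self.wavenumbers.copy(), self.intensities.copy(), self.meta.copy())

    def area(self) -> float:
        """Trapezoidal area over the axis."""
        return float(np.trapezoid(self.intensities, self.wavenumbers))

    def with_intensities(self, intensities) -> "RamanSpectrum":
        return RamanSpectrum(self.wavenumbers, np.asarray(intensities, float), self.meta.copy())


class SpectraDataset:
    """All spectra of an aging experiment on a common wavenumber grid."""

    def __init__(self, spectra: Sequence[RamanSpectrum]):
        spectra = list(spectra)
        if not spectra:
            raise ValueError("empty dataset")
        axis = spectra[0].wavenumbers
        for i, s in enumerate(spectra):
            if s.wavenumbers.shape != axis.shape or not np.allclose(
                s.wavenumbers, axis, rtol=0, atol=1e-9
            ):
                raise ValueError(
                    f"spectrum {i} is not on the common axis; harmonize() first"
                )
        self.spectra = spectra
        self.common_axis = axis

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    @property
    def matrix(self) -> np.ndarray:
        """Spectra-by-channels matrix aligned to ``common_axis``."""
        return np.vstack([s.intensities for s in self.spectra])

    @property
    def hours(self) -> np.ndarray:
        return np.array([s.meta.hour for s in self.spectra])

    @property
    def donor_ids(self) -> list:
        return [s.meta.donor_id for s in self.spectra]

    @property
    def schedule(self) -> list:
        """Sorted distinct hours present in the dataset."""
        return sorted(set(float(s.meta.hour) for s in self.spectra))

    @property
    def donors(self) -> list:
        seen: dict = {}
        for s in self.spectra:
            seen.setdefault(s.meta.donor_id, None)
        return list(seen)

    def select(self, donor_id=None, hour=None, exclude_flags: Iterable[str] = ()) -> "SpectraDataset":
        excl = set(exclude_flags)
        keep = [
            s
            for s in self.spectra
            if (donor_id is None or s.meta.donor_id == donor_id)
            and (hour is None or s.meta.hour == hour)
            and not (excl & s.meta.flags)
        ]
        if not keep:
            raise ValueError("selection is empty")
        return SpectraDataset(keep)

    def map_groups(self):
        """Yield ((donor_id, hour), [spectra]) for every acquisition map."""
        groups: dict = {}
        for s in self.spectra:
            groups.setdefault((s.meta.donor_id, float(s.meta.hour)), []).append(s)
        for key in sorted(groups):
            yield key, groups[key]


@dataclass
class ManifestRow:
    path: str
    donor_id: str
    hour: float
    spot_index: int


@dataclass
class ExperimentManifest:
    """Rows associating spectrum files with donor / hour / spot labels."""

    rows: list

    def __post_init__(self):
        triples = [(r.donor_id, r.hour, r.spot_index) for r in self.rows]
        if len(set(triples)) != len(triples):
            raise ValueError("(donor, hour, spot) triples must be unique")


def read_spectrum(path, meta: SpectrumMeta | None = None) -> RamanSpectrum:
    """Read a two-column delimited (CSV or whitespace) spectrum file.

    Rows stored in descending wavenumber order are reordered ascending.
    A single non-numeric header line is tolerated.
    """
    path = Path(path)
    wn, it = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {len(parts)}")
            try:
                w, v = float(parts[0]), float(parts[1])
            except ValueError:
                if lineno == 1 and not wn:  # header
                    continue
                raise ValueError(f"{path}:{lineno}: malformed row {line!r}") from None
            wn.append(w)
            it.append(v)
    wn_arr = np.array(wn)
    it_arr = np.array(it)
    if wn_arr.size >= 2 and np.all(np.diff(wn_arr) < 0):
        wn_arr, it_arr = wn_arr[::-1], it_arr[::-1]
    try:
        return RamanSpectrum(wn_arr, it_arr, meta)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def write_spectrum(spectrum: RamanSpectrum, path) -> None:
    """Write a spectrum as CSV with full float precision."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("wavenumber_cm-1,intensity\n")
        for w, v in zip(spectrum.wavenumbers, spectrum.intensities):
            fh.write(f"{float(w)!r},{float(v)!r}\n")


def read_manifest(path) -> ExperimentManifest:
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
                rows.append(
                    ManifestRow(
                        path=str(obj["path"]),
                        donor_id=str(obj["donor_id"]),
                        hour=float(obj["hour"]),
                        spot_index=int(obj["spot_index"]),
                    )
                )
            except (json.JSONDecodeError, KeyError) as exc:
                raise ValueError(f"{path}:{lineno}: bad manifest row ({exc})") from None
    return ExperimentManifest(rows)


def write_manifest(manifest: ExperimentManifest, path) -> None:
    with open(path, "w") as fh:
        for r in manifest.rows:
            fh.write(
                json.dumps(
                    {
                        "path": r.path,
                        "donor_id": r.donor_id,
                        "hour": r.hour,
                        "spot_index": r.spot_index,
                    }
                )
                + "\n"
            )


def read_dataset(manifest_path) -> SpectraDataset:
    """Load every spectrum referenced by a manifest (paths relative to it)."""
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    base = manifest_path.parent
    spectra = []
    for r in manifest.rows:
        p = base / r.path
        if not p.exists():
            raise FileNotFoundError(f"manifest references missing file {p}")
        spectra.append(
            read_spectrum(p, SpectrumMeta(r.donor_id, r.hour, r.spot_index))
        )
    return SpectraDataset(spectra)


def write_dataset(dataset: SpectraDataset, out_dir, manifest_name: str = "manifest.jsonl"):
    """Write one CSV per spectrum plus a JSON-lines manifest; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in dataset.spectra:
        m = s.meta
        fname = f"{m.donor_id}_h{m.hour:g}_s{m.spot_index:02d}.csv"
        write_spectrum(s, out_dir / fname)
        rows.append(ManifestRow(fname, m.donor_id, m.hour, m.spot_index))
    manifest = ExperimentManifest(rows)
    write_manifest(manifest, out_dir / manifest_name)
    return out_dir / manifest_name


def harmonize(dataset: SpectraDataset, grid) -> SpectraDataset:
    """Linearly interpolate every spectrum onto ``grid``.

    Idempotent on its own output.  Raises if ``grid`` falls outside a
    spectrum's span (no extrapolation).
    """
    grid = np.asarray(grid, dtype=float)
    out = []
    for i, s in enumerate(dataset.spectra):
        if grid[0] < s.wavenumbers[0] - 1e-9 or grid[-1] > s.wavenumbers[-1] + 1e-9:
            raise ValueError(
                f"grid [{grid[0]:g}, {grid[-1]:g}] outside span of spectrum {i} ({s!r})"
            )
        out.append(
            RamanSpectrum(grid, np.interp(grid, s.wavenumbers, s.intensities), s.meta.copy())
        )
    return SpectraDataset(out)
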