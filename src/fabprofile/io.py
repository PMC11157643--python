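"""Input/output and configuration for the Fab-profiling pipeline.

Handles three on-disk formats:

* **mzML** (read and write) — MS1, profile-mode runs.  Only the subset of
  mzML 1.1 needed here is supported: spectra with an ms-level, a scan start
  time and base64-encoded m/z + intensity arrays (32- or 64-bit floats,
  zlib-compressed or raw).  Implemented on the standard library.
* **clone tables** — plain TSV with the fixed header
  ``clone_id  mass_da  rt_min  intensity  n_slices``; the per-sample
  deliverable of the pipeline.
* **similarity matrices** — CSV with sample ids as row/column labels.

Plus a flat ``key = value`` configuration format whose defaults reproduce
the published timsTOF processing settings.
"""

from __future__ import annotations

import base64
import hashlib
import math
import struct
import zlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Sequence
from xml.etree import ElementTree as ET

import numpy as np
import pandas as pd

from .clones import Clone, ClonalProfile
from .errors import ConfigError, EmptyRunError, MzmlParseError, SchemaError

__all__ = [
    "Spectrum",
    "Run",
    "PipelineConfig",
    "load_config",
    "config_hash",
    "mz_grid",
    "mass_grid",
    "read_mzml",
    "write_mzml",
    "read_clone_table",
    "write_clone_table",
    "read_similarity_matrix",
    "write_similarity_matrix",
]


# --------------------------------------------------------------------------
# domain containers
# --------------------------------------------------------------------------

@dataclass
class Spectrum:
    """One profile-mode m/z–intensity trace.

    ``rt`` is the retention time in minutes (window midpoint for averaged
    slices).  ``mz`` must be strictly increasing and ``intensity``
    non-negative, same length.
    """

    rt: float
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)

    def validate(self) -> None:
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity lengths differ")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("mz values are not strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("negative intensities")


@dataclass
class Run:
    """An ordered set of MS1 spectra with retention times."""

    run_id: str
    scans: list[Spectrum] = field(default_factory=list)
    mz_low: float = 500.0
    mz_high: float = 3000.0
    scan_rate_hz: float = 1.0
    centroided: bool = False  # flagged when the source stored centroid spectra

    def __len__(self) -> int:
        return len(self.scans)

    def retention_times(self) -> np.ndarray:
        return np.array([s.rt for s in self.scans])

    def validate(self) -> None:
        rts = self.retention_times()
        if rts.size > 1 and not np.all(np.diff(rts) > 0):
            raise ValueError("scan retention times are not strictly increasing")
        for s in self.scans:
            s.validate()


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """All tunable pipeline parameters.

    Defaults are the published timsTOF processing settings: 10–50 min region
    of interest cut into 0.3 min slices with 0.05 min overlap, baseline
    flatness 0.8, one pass of 0.2 Th Gaussian smoothing, deconvolution over
    m/z 500–3000 onto a 45–52 kDa mass grid with 0.1 Da spacing at an
    instrument resolving power of 10000, Sum-Peak-style picking at resolving
    power 6500 with an absolute intensity threshold of 500, and 50 ppm slice
    merging.  ``merge_max_rt_gap`` is unbounded by default; setting
    ``merge_ppm = 30`` and ``merge_max_rt_gap = 2`` reproduces the
    Orbitrap-style merge.
    """

    # region of interest / slicing (minutes)
    roi_start: float = 10.0
    roi_end: float = 50.0
    slice_width: float = 0.3
    slice_overlap: float = 0.05
    # per-slice preprocessing
    baseline_flatness: float = 0.8
    smooth_width: float = 0.2          # Th, FWHM of the Gaussian kernel
    smooth_iterations: int = 1
    # observed m/z domain
    mz_low: float = 500.0
    mz_high: float = 3000.0
    mz_spacing: float = 0.1            # Th, common resampling grid
    # zero-charge mass domain
    mass_low: float = 45000.0
    mass_high: float = 52000.0
    mass_spacing: float = 0.1          # Da
    instrument_resolving_power: float = 10000.0
    charge_min: int = 12
    charge_max: int = 60
    # peak picking
    peak_resolving_power: float = 6500.0
    peak_intensity_threshold: float = 500.0
    # slice merging
    merge_ppm: float = 50.0
    merge_max_rt_gap: float = math.inf  # minutes
    # similarity scoring
    similarity_top_n: int = 100
    similarity_tolerance: float = 1.5   # Da
    # physical constant
    proton_mass: float = 1.007276       # Da
    # deconvolution solver
    max_iterations: int = 100
    convergence_tol: float = 1e-4

    def validate(self) -> None:
        c = self
        checks = [
            (c.roi_start < c.roi_end, "roi_start", "roi_start must be < roi_end"),
            (0 < c.slice_overlap < c.slice_width, "slice_overlap",
             "slice_overlap must satisfy 0 < overlap < slice_width"),
            (0 < c.baseline_flatness <= 1, "baseline_flatness",
             "baseline_flatness must lie in (0, 1]"),
            (c.smooth_width > 0, "smooth_width", "smooth_width must be > 0"),
            (c.smooth_iterations >= 0, "smooth_iterations",
             "smooth_iterations must be >= 0"),
            (c.mz_low < c.mz_high, "mz_low", "mz_low must be < mz_high"),
            (c.mz_spacing > 0, "mz_spacing", "mz_spacing must be > 0"),
            (c.mass_low < c.mass_high, "mass_low", "mass_low must be < mass_high"),
            (c.mass_spacing > 0, "mass_spacing", "mass_spacing must be > 0"),
            (c.instrument_resolving_power > 0, "instrument_resolving_power",
             "instrument_resolving_power must be > 0"),
            (1 <= c.charge_min <= c.charge_max, "charge_min",
             "charges must satisfy 1 <= charge_min <= charge_max"),
            (c.peak_resolving_power > 0, "peak_resolving_power",
             "peak_resolving_power must be > 0"),
            (c.peak_intensity_threshold >= 0, "peak_intensity_threshold",
             "peak_intensity_threshold must be >= 0"),
            (c.merge_ppm > 0, "merge_ppm", "merge_ppm must be > 0"),
            (c.merge_max_rt_gap > 0, "merge_max_rt_gap",
             "merge_max_rt_gap must be > 0"),
            (c.similarity_top_n >= 1, "similarity_top_n",
             "similarity_top_n must be >= 1"),
            (c.similarity_tolerance > 0, "similarity_tolerance",
             "similarity_tolerance must be > 0"),
            (c.proton_mass > 0, "proton_mass", "proton_mass must be > 0"),
            (c.max_iterations >= 1, "max_iterations", "max_iterations must be >= 1"),
            (c.convergence_tol > 0, "convergence_tol", "convergence_tol must be > 0"),
        ]
        for ok, key, msg in checks:
            if not ok:
                raise ConfigError(f"{key}: {msg}")


_INT_KEYS = {"smooth_iterations", "charge_min", "charge_max",
             "similarity_top_n", "max_iterations"}
_UNBOUNDED = {"inf", "unbounded", "none"}


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a pipeline configuration from a flat ``key = value`` file.

    Blank lines and ``#`` comments are ignored.  Keys absent from the file
    keep the published timsTOF defaults.  ``merge_max_rt_gap`` accepts
    ``inf``/``unbounded``.  Keyword arguments override file values.
    """
    values: dict = {}
    known = {f.name for f in fields(PipelineConfig)}
    if path is not None:
        text = Path(path).read_text()
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" in line:
                key, _, val = line.partition("=")
            else:
                parts = line.split(None, 1)
                if len(parts) != 2:
                    raise ConfigError(f"line {lineno}: expected 'key = value', got {raw!r}")
                key, val = parts
            key, val = key.strip(), val.strip()
            if key not in known:
                raise ConfigError(f"line {lineno}: unknown key {key!r}")
            values[key] = _parse_value(key, val, lineno)
    values.update(overrides)
    cfg = PipelineConfig(**values)
    cfg.validate()
    return cfg


def _parse_value(key: str, val: str, lineno: int):
    if key == "merge_max_rt_gap" and val.lower() in _UNBOUNDED:
        return math.inf
    try:
        return int(val) if key in _INT_KEYS else float(val)
    except ValueError:
        raise ConfigError(f"line {lineno}: key {key!r} has non-numeric value {val!r}") from None


def config_hash(config: PipelineConfig) -> str:
    """Short stable hash of the full parameter set, for provenance."""
    canon = ";".join(f"{k}={v!r}" for k, v in sorted(asdict(config).items()))
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def mz_grid(config: PipelineConfig) -> np.ndarray:
    """Uniform m/z resampling grid implied by the configuration."""
    n = int(round((config.mz_high - config.mz_low) / config.mz_spacing)) + 1
    return config.mz_low + config.mz_spacing * np.arange(n)


def mass_grid(config: PipelineConfig) -> np.ndarray:
    """Uniform zero-charge mass grid implied by the configuration."""
    n = int(round((config.mass_high - config.mass_low) / config.mass_spacing)) + 1
    return config.mass_low + config.mass_spacing * np.arange(n)


# --------------------------------------------------------------------------
# mzML
# --------------------------------------------------------------------------

_NS = "http://psi.hupo.org/ms/mzml"

# controlled-vocabulary accessions used by the reader/writer
_ACC_MS_LEVEL = "MS:1000511"
_ACC_PROFILE = "MS:1000128"
_ACC_CENTROID = "MS:1000127"
_ACC_SCAN_START = "MS:1000016"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_NOCOMP = "MS:1000576"
_ACC_UNIT_MINUTE = "UO:0000031"
_ACC_UNIT_SECOND = "UO:0000010"


def _strip(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_binary(bda: ET.Element, n_expected: int, spec_id: str) -> tuple[np.ndarray, str | None]:
    dtype = None
    compressed = False
    kind = None
    for cv in bda.iter():
        if _strip(cv.tag) != "cvParam":
            continue
        acc = cv.get("accession", "")
        if acc == _ACC_F64:
            dtype = "<d"
        elif acc == _ACC_F32:
            dtype = "<f"
        elif acc == _ACC_ZLIB:
            compressed = True
        elif acc == _ACC_NOCOMP:
            compressed = False
        elif acc == _ACC_MZ_ARRAY:
            kind = "mz"
        elif acc == _ACC_INT_ARRAY:
            kind = "intensity"
    binary = bda.find(f"{{{_NS}}}binary")
    if binary is None:
        for child in bda:
            if _strip(child.tag) == "binary":
                binary = child
                break
    if binary is None:
        raise MzmlParseError(f"spectrum {spec_id!r}: binaryDataArray without <binary>")
    raw = base64.b64decode(binary.text or "")
    if compressed:
        try:
            raw = zlib.decompress(raw)
        except zlib.error as exc:
            raise MzmlParseError(f"spectrum {spec_id!r}: zlib decompression failed") from exc
    if dtype is None:
        raise MzmlParseError(f"spectrum {spec_id!r}: binary array lacks a float-type cvParam")
    itemsize = struct.calcsize(dtype)
    if len(raw) % itemsize:
        raise MzmlParseError(f"spectrum {spec_id!r}: binary payload length not a multiple of {itemsize}")
    arr = np.frombuffer(raw, dtype=np.dtype(dtype)).astype(np.float64)
    if n_expected and arr.size != n_expected:
        raise MzmlParseError(
            f"spectrum {spec_id!r}: defaultArrayLength {n_expected} but decoded {arr.size} values"
        )
    return arr, kind


def read_mzml(path: str | Path) -> Run:
    """Read an MS1, profile-mode mzML file into a :class:`Run`.

    MS2+ spectra are ignored.  Scans are returned sorted by retention time
    regardless of file order.  Centroid-mode spectra are accepted but the
    run is flagged ``centroided``.
    """
    path = Path(path)
    scans: list[Spectrum] = []
    centroided = False
    saw_spectrum = False
    try:
        context = ET.iterparse(str(path), events=("end",))
        for _event, elem in context:
            if _strip(elem.tag) != "spectrum":
                continue
            saw_spectrum = True
            spec_id = elem.get("id", "?")
            n_expected = int(elem.get("defaultArrayLength", "0"))
            ms_level = None
            rt = None
            is_centroid = False
            for cv in elem.iter():
                if _strip(cv.tag) != "cvParam":
                    continue
                acc = cv.get("accession", "")
                if acc == _ACC_MS_LEVEL:
                    ms_level = int(cv.get("value", "0"))
                elif acc == _ACC_CENTROID:
                    is_centroid = True
                elif acc == _ACC_SCAN_START:
                    rt = float(cv.get("value", "nan"))
                    if cv.get("unitAccession") == _ACC_UNIT_SECOND or \
                            cv.get("unitName", "").lower() == "second":
                        rt /= 60.0
            if ms_level != 1:
                elem.clear()
                continue
            if rt is None or math.isnan(rt):
                raise MzmlParseError(f"spectrum {spec_id!r}: no scan start time")
            mz = intensity = None
            for bda in elem.iter():
                if _strip(bda.tag) != "binaryDataArray":
                    continue
                arr, kind = _decode_binary(bda, n_expected, spec_id)
                if kind == "mz":
                    mz = arr
                elif kind == "intensity":
                    intensity = arr
            if mz is None or intensity is None:
                raise MzmlParseError(f"spectrum {spec_id!r}: missing m/z or intensity array")
            if mz.size != intensity.size:
                raise MzmlParseError(f"spectrum {spec_id!r}: m/z and intensity lengths differ")
            centroided |= is_centroid
            scans.append(Spectrum(rt=rt, mz=mz, intensity=intensity))
            elem.clear()
    except ET.ParseError as exc:
        raise MzmlParseError(f"{path.name}: malformed XML ({exc})") from exc
    if not scans:
        if saw_spectrum:
            raise EmptyRunError(f"{path.name}: no MS1 spectra (MS2-only file?)")
        raise EmptyRunError(f"{path.name}: no spectra found")
    scans.sort(key=lambda s: s.rt)
    mz_lo = float(min(s.mz[0] for s in scans if s.mz.size))
    mz_hi = float(max(s.mz[-1] for s in scans if s.mz.size))
    rts = [s.rt for s in scans]
    rate = 1.0
    if len(rts) > 1:
        dt = np.median(np.diff(rts)) * 60.0
        if dt > 0:
            rate = 1.0 / dt
    return Run(run_id=path.stem, scans=scans, mz_low=mz_lo, mz_high=mz_hi,
               scan_rate_hz=rate, centroided=centroided)


def _b64(arr: np.ndarray, compress: bool) -> str:
    raw = np.asarray(arr, dtype="<f8").tobytes()
    if compress:
        raw = zlib.compress(raw, level=6)
    return base64.b64encode(raw).decode("ascii")


def write_mzml(run: Run, path: str | Path, compress: bool = True) -> None:
    """Write a :class:`Run` as a minimal MS1 profile-mode mzML file."""
    path = Path(path)
    parts: list[str] = []
    parts.append('<?xml version="1.0" encoding="utf-8"?>\n')
    parts.append(f'<mzML xmlns="{_NS}" version="1.1.0">\n')
    parts.append(
        '  <cvList count="2">\n'
        '    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology"'
        ' URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>\n'
        '    <cv id="UO" fullName="Unit Ontology"'
        ' URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>\n'
        '  </cvList>\n'
    )
    parts.append(
        '  <fileDescription><fileContent>'
        '<cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>'
        '</fileContent></fileDescription>\n'
    )
    comp_acc, comp_name = (_ACC_ZLIB, "zlib compression") if compress else \
        (_ACC_NOCOMP, "no compression")
    parts.append(f'  <run id="{run.run_id}">\n')
    parts.append(f'    <spectrumList count="{len(run.scans)}">\n')
    mode_acc, mode_name = (_ACC_CENTROID, "centroid spectrum") if run.centroided \
        else (_ACC_PROFILE, "profile spectrum")
    for i, scan in enumerate(run.scans):
        n = scan.mz.size
        parts.append(
            f'      <spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{n}">\n'
            f'        <cvParam cvRef="MS" accession="{_ACC_MS_LEVEL}" name="ms level" value="1"/>\n'
            f'        <cvParam cvRef="MS" accession="{mode_acc}" name="{mode_name}" value=""/>\n'
            f'        <scanList count="1"><scan>'
            f'<cvParam cvRef="MS" accession="{_ACC_SCAN_START}" name="scan start time" '
            f'value="{scan.rt!r}" unitCvRef="UO" unitAccession="{_ACC_UNIT_MINUTE}" '
            f'unitName="minute"/></scan></scanList>\n'
            f'        <binaryDataArrayList count="2">\n'
        )
        for arr, acc, name in ((scan.mz, _ACC_MZ_ARRAY, "m/z array"),
                               (scan.intensity, _ACC_INT_ARRAY, "intensity array")):
            b64 = _b64(arr, compress)
            parts.append(
                f'          <binaryDataArray encodedLength="{len(b64)}">\n'
                f'            <cvParam cvRef="MS" accession="{_ACC_F64}" name="64-bit float" value=""/>\n'
                f'            <cvParam cvRef="MS" accession="{comp_acc}" name="{comp_name}" value=""/>\n'
                f'            <cvParam cvRef="MS" accession="{acc}" name="{name}" value=""/>\n'
                f'            <binary>{b64}</binary>\n'
                f'          </binaryDataArray>\n'
            )
        parts.append('        </binaryDataArrayList>\n      </spectrum>\n')
    parts.append('    </spectrumList>\n  </run>\n</mzML>\n')
    path.write_text("".join(parts))


# --------------------------------------------------------------------------
# clone tables
# --------------------------------------------------------------------------

_CLONE_COLUMNS = ["clone_id", "mass_da", "rt_min", "intensity", "n_slices"]


def write_clone_table(profile: ClonalProfile, path: str | Path) -> None:
    """Write a clonal profile as a TSV clone table."""
    profile.validate()
    path = Path(path)
    lines = ["\t".join(_CLONE_COLUMNS)]
    for c in profile.clones:
        lines.append(
            f"{c.clone_id}\t{c.mass:.4f}\t{c.rt:.4f}\t{c.intensity:.6g}\t{c.n_slices}"
        )
    path.write_text("\n".join(lines) + "\n")


def read_clone_table(path: str | Path, sample_id: str | None = None) -> ClonalProfile:
    """Read a TSV clone table back into a :class:`ClonalProfile`."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:
        raise SchemaError(f"{path.name}: unreadable clone table ({exc})") from exc
    if list(df.columns) != _CLONE_COLUMNS:
        raise SchemaError(
            f"{path.name}: expected columns {_CLONE_COLUMNS}, found {list(df.columns)}"
        )
    clones: list[Clone] = []
    for row_idx, row in enumerate(df.itertuples(index=False), start=2):
        try:
            clone = Clone(
                clone_id=int(row.clone_id),
                mass=float(row.mass_da),
                rt=float(row.rt_min),
                intensity=float(row.intensity),
                n_slices=int(row.n_slices),
            )
        except (TypeError, ValueError):
            raise SchemaError(f"{path.name}: row {row_idx}: non-numeric cell") from None
        if clone.intensity < 0:
            raise SchemaError(f"{path.name}: row {row_idx}: negative intensity")
        if clone.n_slices < 1:
            raise SchemaError(f"{path.name}: row {row_idx}: n_slices < 1")
        clones.append(clone)
    profile = ClonalProfile(sample_id=sample_id or path.stem, clones=clones)
    profile.validate()
    return profile


# --------------------------------------------------------------------------
# similarity matrices
# --------------------------------------------------------------------------

def write_similarity_matrix(sample_ids: Sequence[str], scores: np.ndarray,
                            path: str | Path) -> None:
    """Write a square similarity matrix as labelled CSV."""
    scores = np.asarray(scores, dtype=np.float64)
    if scores.shape != (len(sample_ids), len(sample_ids)):
        raise ValueError("scores shape does not match sample_ids")
    df = pd.DataFrame(scores, index=list(sample_ids), columns=list(sample_ids))
    df.to_csv(path, float_format="%.6f")


def read_similarity_matrix(path: str | Path) -> tuple[list[str], np.ndarray]:
    path = Path(path)
    try:
        df = pd.read_csv(path, index_col=0)
    except Exception as exc:
        raise SchemaError(f"{path.name}: unreadable similarity matrix ({exc})") from exc
    if list(df.index) != list(df.columns):
        raise SchemaError(f"{path.name}: row and column labels differ")
    return list(df.columns), df.to_numpy(dtype=np.float64)
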