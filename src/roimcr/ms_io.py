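"""Readers/writers for the formats the pipeline touches.

Internal conventions: retention time is always seconds from run start,
m/z is always Da. Unit conversions happen only at the I/O boundary.
"""

from __future__ import annotations

import base64
import json
from dataclasses import dataclass, field
from pathlib import Path
from xml.sax.saxutils import escape

import numpy as np
import pandas as pd

__all__ = [
    "ScanSet",
    "FeatureTable",
    "read_scans",
    "write_mzml",
    "read_feature_table",
    "write_feature_table",
    "save_arrays",
    "load_arrays",
]


@dataclass
class ScanSet:
    """One sample's centroided chromatographic run.

    Scans are stored as parallel sequences: ``rts[i]`` (seconds) with the
    centroid arrays ``mzs[i]`` / ``intensities[i]`` (sorted by m/z).
    """

    sample_id: str
    rts: np.ndarray
    mzs: list
    intensities: list
    ionization_mode: str = "+"

    def __post_init__(self):
        self.rts = np.asarray(self.rts, dtype=float)
        order = np.argsort(self.rts, kind="stable")
        if not np.all(order == np.arange(len(order))):
            self.rts = self.rts[order]
            self.mzs = [self.mzs[i] for i in order]
            self.intensities = [self.intensities[i] for i in order]
        for i in range(self.n_scans):
            mz = np.asarray(self.mzs[i], dtype=float)
            inten = np.asarray(self.intensities[i], dtype=float)
            if mz.size and np.any(np.diff(mz) < 0):
                o = np.argsort(mz, kind="stable")
                mz, inten = mz[o], inten[o]
            self.mzs[i] = mz
            self.intensities[i] = inten

    @property
    def n_scans(self) -> int:
        return len(self.rts)

    def tic(self) -> np.ndarray:
        """Total ion current per scan."""
        return np.array([inten.sum() if inten.size else 0.0 for inten in self.intensities])

    def total_intensity(self) -> float:
        return float(self.tic().sum())


@dataclass
class FeatureTable:
    """Feature-profiling output: (m/z, RT) rows with per-sample areas.

    ``data`` is indexed by feature id with columns ``mz`` (Da), ``rt``
    (seconds) and one area column per sample.
    """

    data: pd.DataFrame
    sample_ids: list = field(default_factory=list)

    def __post_init__(self):
        if not self.sample_ids:
            self.sample_ids = [c for c in self.data.columns if c not in ("mz", "rt")]
        if self.data.index.has_duplicates:
            raise ValueError("duplicate feature ids")
        if len(self.data) and (self.data["mz"] <= 0).any():
            raise ValueError("m/z must be positive")
        areas = self.data[self.sample_ids]
        if len(self.data) and (areas.fillna(0).to_numpy() < 0).any():
            raise ValueError("areas must be non-negative")

    @property
    def n_features(self) -> int:
        return len(self.data)

    def areas(self) -> pd.DataFrame:
        """Samples x features area matrix (missing as 0)."""
        return self.data[self.sample_ids].T.fillna(0.0)


# ---------------------------------------------------------------------------
# scan data


def _decode_binary(text: str, dtype: str, compressed: bool) -> np.ndarray:
    raw = base64.b64decode(text)
    if compressed:
        import zlib

        raw = zlib.decompress(raw)
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _read_mzml(path) -> tuple:
    """Minimal centroid-mzML reader (stdlib iterparse, MS1 spectra only)."""
    import xml.etree.ElementTree as ET

    rts, mzs, intens = [], [], []
    for _event, elem in ET.iterparse(str(path), events=("end",)):
        if _local(elem.tag) != "spectrum":
            continue
        params = {}
        for cv in elem.iter():
            if _local(cv.tag) == "cvParam":
                params.setdefault(cv.get("name"), cv)
        if "profile spectrum" in params:
            raise ValueError("centroided data required (profile-mode spectrum found)")
        rt_param = params.get("scan start time")
        if rt_param is None:
            elem.clear()
            continue
        rt = float(rt_param.get("value"))
        if rt_param.get("unitName", "second").startswith("min"):
            rt *= 60.0
        arrays = {}
        for bda in elem.iter():
            if _local(bda.tag) != "binaryDataArray":
                continue
            dtype, compressed, kind, text = "<f8", False, None, ""
            for child in bda.iter():
                tag = _local(child.tag)
                if tag == "cvParam":
                    name = child.get("name")
                    if name == "32-bit float":
                        dtype = "<f4"
                    elif name == "64-bit float":
                        dtype = "<f8"
                    elif name == "zlib compression":
                        compressed = True
                    elif name in ("m/z array", "intensity array"):
                        kind = name
                elif tag == "binary":
                    text = child.text or ""
            if kind:
                arrays[kind] = _decode_binary(text, dtype, compressed)
        rts.append(rt)
        mzs.append(arrays.get("m/z array", np.zeros(0)))
        intens.append(arrays.get("intensity array", np.zeros(0)))
        elem.clear()
    return rts, mzs, intens


def _read_mzxml(path) -> tuple:
    """Minimal centroid-mzXML reader (network-order interleaved peaks)."""
    import re
    import xml.etree.ElementTree as ET

    rts, mzs, intens = [], [], []
    for _event, elem in ET.iterparse(str(path), events=("end",)):
        if _local(elem.tag) != "scan":
            continue
        if elem.get("centroided", "1") in ("0", "false", "False"):
            raise ValueError("centroided data required (profile-mode spectrum found)")
        rt_attr = elem.get("retentionTime", "PT0S")
        m = re.fullmatch(r"PT(?:(\d+(?:\.\d+)?)M)?(?:(\d+(?:\.\d+)?)S)?", rt_attr)
        if m:
            rt = 60.0 * float(m.group(1) or 0) + float(m.group(2) or 0)
        else:
            rt = float(rt_attr)
        pair = np.zeros(0)
        for child in elem.iter():
            if _local(child.tag) == "peaks":
                dtype = ">f4" if child.get("precision", "32") == "32" else ">f8"
                compressed = child.get("compressionType", "none") == "zlib"
                pair = _decode_binary(child.text or "", dtype, compressed)
        rts.append(rt)
        mzs.append(pair[0::2])
        intens.append(pair[1::2])
        elem.clear()
    return rts, mzs, intens


def read_scans(path, fmt: str | None = None, sample_id: str | None = None) -> ScanSet:
    """Read a centroided mzML/mzXML run into a :class:`ScanSet`.

    Profile-mode spectra are rejected: the pipeline consumes centroided
    data only. Scans are sorted by retention time on read.
    """
    path = Path(path)
    if fmt is None:
        fmt = "mzxml" if path.suffix.lower() == ".mzxml" else "mzml"
    if fmt == "mzml":
        rts, mzs, intens = _read_mzml(path)
    elif fmt == "mzxml":
        rts, mzs, intens = _read_mzxml(path)
    else:
        raise ValueError(f"unknown scan format: {fmt!r}")
    if not rts:
        raise ValueError(f"empty run: {path}")
    return ScanSet(sample_id or path.stem, np.array(rts), mzs, intens)


def _b64(arr: np.ndarray) -> str:
    return base64.b64encode(np.asarray(arr, dtype="<f8").tobytes()).decode("ascii")


_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="1">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
      <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
    </fileContent>
  </fileDescription>
  <run id="{run_id}">
    <spectrumList count="{count}">
"""

_MZML_SPECTRUM = """      <spectrum index="{idx}" id="scan={idx}" defaultArrayLength="{npts}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
        <cvParam cvRef="MS" accession="MS:{polarity}" name="{polarity_name}" value=""/>
        <scanList count="1">
          <scan>
            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{rt}" unitCvRef="UO" unitAccession="UO:0000010" unitName="second"/>
          </scan>
        </scanList>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{len_mz}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
            <binary>{b64_mz}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{len_int}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
            <binary>{b64_int}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
"""

_MZML_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def write_mzml(scanset: ScanSet, path) -> Path:
    """Write a ScanSet as a minimal centroid-mode mzML file."""
    path = Path(path)
    pol = ("1000130", "positive scan") if scanset.ionization_mode == "+" else ("1000129", "negative scan")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_MZML_HEADER.format(run_id=escape(scanset.sample_id), count=scanset.n_scans))
        for i in range(scanset.n_scans):
            b64_mz = _b64(scanset.mzs[i])
            b64_int = _b64(scanset.intensities[i])
            fh.write(
                _MZML_SPECTRUM.format(
                    idx=i,
                    npts=scanset.mzs[i].size,
                    rt=repr(float(scanset.rts[i])),
                    polarity=pol[0],
                    polarity_name=pol[1],
                    len_mz=len(b64_mz),
                    b64_mz=b64_mz,
                    len_int=len(b64_int),
                    b64_int=b64_int,
                )
            )
        fh.write(_MZML_FOOTER)
    return path


# ---------------------------------------------------------------------------
# feature tables

_MZMINE3_COLUMNS = {"id": "row ID", "mz": "row m/z", "rt": "row retention time"}
_MZMINE3_AREA_SUFFIX = " Peak area"


def read_feature_table(path, dialect: str = "generic", rt_unit: str = "seconds") -> FeatureTable:
    """Read a feature CSV in one of two dialects.

    ``generic``: columns ``feature_id`` (optional), ``mz``, ``rt`` plus one
    area column per sample; ``rt_unit`` declares the RT unit of the file.
    ``mzmine3-export``: the aligned-feature-list CSV layout with ``row ID``,
    ``row m/z``, ``row retention time`` (minutes) and ``<raw file> Peak
    area`` columns.
    """
    df = pd.read_csv(path)
    if dialect == "mzmine3-export":
        missing = [c for c in _MZMINE3_COLUMNS.values() if c not in df.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")
        area_cols = [c for c in df.columns if c.endswith(_MZMINE3_AREA_SUFFIX)]
        out = pd.DataFrame(
            {
                "mz": df[_MZMINE3_COLUMNS["mz"]].astype(float),
                "rt": df[_MZMINE3_COLUMNS["rt"]].astype(float) * 60.0,  # exported in minutes
            }
        )
        for c in area_cols:
            sample = c[: -len(_MZMINE3_AREA_SUFFIX)]
            if sample.lower().endswith((".mzml", ".mzxml", ".raw")):
                sample = sample.rsplit(".", 1)[0]
            out[sample] = df[c].astype(float)
        out.index = pd.Index(df[_MZMINE3_COLUMNS["id"]].astype(str), name="feature_id")
    elif dialect == "generic":
        missing = [c for c in ("mz", "rt") if c not in df.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")
        if "feature_id" in df.columns:
            df = df.set_index(df["feature_id"].astype(str)).drop(columns="feature_id")
        else:
            df.index = pd.Index([f"f{i}" for i in range(len(df))], name="feature_id")
        out = df.copy()
        out["mz"] = out["mz"].astype(float)
        factor = {"seconds": 1.0, "minutes": 60.0}[rt_unit]
        out["rt"] = out["rt"].astype(float) * factor
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")
    if out.index.has_duplicates:
        raise ValueError("duplicate feature ids")
    out.index = out.index.astype(str)
    return FeatureTable(out)


def write_feature_table(table: FeatureTable, path) -> Path:
    path = Path(path)
    df = table.data.copy()
    df.insert(0, "feature_id", df.index)
    df.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# model containers: JSON metadata next to an .npz of arrays


def save_arrays(meta: dict, arrays: dict, stem) -> tuple[Path, Path]:
    """Write a JSON+NPZ container (deterministic key order)."""
    stem = Path(stem)
    jpath = stem.with_suffix(".json")
    apath = stem.with_suffix(".npz")
    with open(jpath, "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
    np.savez(apath, **{k: arrays[k] for k in sorted(arrays)})
    return jpath, apath


def load_arrays(stem) -> tuple[dict, dict]:
    stem = Path(stem)
    with open(stem.with_suffix(".json")) as fh:
        meta = json.load(fh)
    with np.load(stem.with_suffix(".npz"), allow_pickle=False) as npz:
        arrays = {k: npz[k] for k in npz.files}
    return meta, arrays
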