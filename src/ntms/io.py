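"""File I/O: mzML, the CSV scan-table dialect, and MSP/MGF libraries.

mzML reading is a direct parse of the mzML 1.1 schema accepting
centroided MS1 data; profile-mode spectra are rejected with an explicit
error.  Writing uses a minimal standards-conforming serializer
(uncompressed 64-bit arrays), sufficient for interchange of synthetic
and fixture runs.

The CSV scan-table dialect is a long-format plain-text fixture format:
comment headers carry run metadata, then one row per centroid with
columns ``scan_index, rt_min, mz, intensity``.  Spectral libraries round
trip through MSP and MGF via matchms.
"""

from __future__ import annotations

import base64
import io as _io
import zlib
from pathlib import Path
from xml.etree import ElementTree as ET
from xml.sax.saxutils import escape

import numpy as np
import pandas as pd

from .chem import ION_SPECIES, ion_mz, parse_formula
from .ms2 import LibraryEntry, MS2Spectrum
from .peaks import Run, Scan

__all__ = [
    "write_mzml",
    "read_mzml",
    "write_scan_table",
    "read_scan_table",
    "read_run",
    "write_table",
    "save_library_msp",
    "load_library_msp",
    "save_library_mgf",
    "load_library_mgf",
]


def _b64(arr: np.ndarray) -> str:
    return base64.b64encode(np.asarray(arr, dtype="<f8").tobytes()).decode()


_POLARITY_CV = {
    "negative": ("MS:1000129", "negative scan"),
    "positive": ("MS:1000130", "positive scan"),
}


def write_mzml(run: Run, path: str | Path) -> None:
    """Serialize a centroided run as (non-indexed) mzML 1.1."""
    pol_acc, pol_name = _POLARITY_CV[run.polarity]
    lines = [
        '<?xml version="1.0" encoding="utf-8"?>',
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">',
        '<cvList count="2">',
        '<cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" '
        'URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>',
        '<cv id="UO" fullName="Unit Ontology" URI="http://ontologies.berkeleybop.org/uo.obo"/>',
        "</cvList>",
        '<fileDescription><fileContent>'
        '<cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>'
        "</fileContent></fileDescription>",
        f'<run id="{escape(run.sample)}">',
        f'<spectrumList count="{len(run.scans)}">',
    ]
    for i, s in enumerate(run.scans):
        mz_b, int_b = _b64(s.mz), _b64(s.intensity)
        lines.append(
            f'<spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{s.mz.size}">'
            '<cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>'
            '<cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>'
            f'<cvParam cvRef="MS" accession="{pol_acc}" name="{pol_name}" value=""/>'
            '<scanList count="1"><scan>'
            f'<cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{s.rt!r}" '
            'unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>'
            "</scan></scanList>"
            '<binaryDataArrayList count="2">'
            f'<binaryDataArray encodedLength="{len(mz_b)}">'
            '<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>'
            '<cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>'
            '<cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" '
            'unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>'
            f"<binary>{mz_b}</binary></binaryDataArray>"
            f'<binaryDataArray encodedLength="{len(int_b)}">'
            '<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>'
            '<cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>'
            '<cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" '
            'unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>'
            f"<binary>{int_b}</binary></binaryDataArray>"
            "</binaryDataArrayList></spectrum>"
        )
    lines += ["</spectrumList>", "</run>", "</mzML>"]
    Path(path).write_text("\n".join(lines))


def _decode_binary_array(bda: ET.Element, ns: str, n: int) -> tuple[str | None, np.ndarray]:
    """Decode one <binaryDataArray>: returns (array kind, float array)."""
    kind = None
    dtype = "<f8"
    compressed = False
    for cv in bda.findall(f"{ns}cvParam"):
        acc = cv.get("accession")
        if acc == "MS:1000514":
            kind = "mz"
        elif acc == "MS:1000515":
            kind = "intensity"
        elif acc == "MS:1000521":
            dtype = "<f4"
        elif acc == "MS:1000523":
            dtype = "<f8"
        elif acc == "MS:1000574":
            compressed = True
    binary = bda.find(f"{ns}binary")
    text = (binary.text or "") if binary is not None else ""
    raw = base64.b64decode(text)
    if compressed:
        raw = zlib.decompress(raw)
    arr = np.frombuffer(raw, dtype=dtype).astype(float)
    if n and arr.size != n:
        raise ValueError(f"binary array length {arr.size} != defaultArrayLength {n}")
    return kind, arr


def read_mzml(path: str | Path, sample: str | None = None, role: str = "sample") -> Run:
    """Read a centroided MS1 mzML file into a Run.

    Uses a direct XML parse of the mzML 1.1 schema (no external mzML
    parser is required); handles 32/64-bit and zlib-compressed binary
    arrays and second- or minute-valued scan start times.  Profile-mode
    spectra raise ``ValueError``; MS2 spectra are skipped.  Truncated or
    malformed XML raises a parse error rather than returning a partial
    run.
    """
    scans: list[Scan] = []
    polarity = "negative"
    ns = "{http://psi.hupo.org/ms/mzml}"
    try:
        tree = ET.parse(str(path))
    except ET.ParseError as e:
        raise ValueError(f"{path}: malformed mzML ({e})") from e
    root = tree.getroot()
    if root.tag not in (f"{ns}mzML", f"{ns}indexedmzML", "mzML", "indexedmzML"):
        raise ValueError(f"{path}: not an mzML document (root {root.tag})")
    if "indexedmzML" in root.tag:
        root = root.find(f"{ns}mzML") or root.find("mzML")
    if root.tag == "mzML":
        ns = ""
    for spec in root.iter(f"{ns}spectrum"):
        params = {cv.get("accession"): cv for cv in spec.findall(f"{ns}cvParam")}
        level = params.get("MS:1000511")
        if level is not None and level.get("value") not in ("1", ""):
            continue
        if "MS:1000128" in params:
            raise ValueError(f"{path}: profile-mode data; centroid before processing")
        if "MS:1000130" in params:
            polarity = "positive"
        elif "MS:1000129" in params:
            polarity = "negative"
        rt = 0.0
        scan_el = spec.find(f"{ns}scanList/{ns}scan")
        if scan_el is not None:
            for cv in scan_el.findall(f"{ns}cvParam"):
                if cv.get("accession") == "MS:1000016":
                    rt = float(cv.get("value"))
                    if cv.get("unitAccession") == "UO:0000010" or cv.get("unitName") == "second":
                        rt /= 60.0
        n = int(spec.get("defaultArrayLength", 0))
        mz = inten = None
        for bda in spec.iter(f"{ns}binaryDataArray"):
            kind, arr = _decode_binary_array(bda, ns, n)
            if kind == "mz":
                mz = arr
            elif kind == "intensity":
                inten = arr
        if mz is None or inten is None:
            raise ValueError(f"{path}: spectrum without m/z or intensity array")
        scans.append(Scan(rt=rt, mz=mz, intensity=inten, polarity=polarity))
    if not scans:
        raise ValueError(f"{path}: no MS1 spectra found")
    for s in scans:
        s.polarity = polarity
    return Run(
        scans=scans,
        sample=sample or Path(path).stem,
        role=role,
        polarity=polarity,
    )


def write_scan_table(run: Run, path: str | Path) -> None:
    """Write the plain-CSV scan-table dialect (long format with metadata)."""
    buf = _io.StringIO()
    buf.write(f"# sample: {run.sample}\n")
    buf.write(f"# role: {run.role}\n")
    buf.write(f"# polarity: {run.polarity}\n")
    buf.write(f"# n_scans: {len(run.scans)}\n")
    buf.write("scan_index,rt_min,mz,intensity\n")
    for i, s in enumerate(run.scans):
        for mz, inten in zip(s.mz, s.intensity):
            buf.write(f"{i},{float(s.rt)!r},{float(mz)!r},{float(inten)!r}\n")
    Path(path).write_text(buf.getvalue())


def read_scan_table(path: str | Path) -> Run:
    """Read the CSV scan-table dialect back into a Run (lossless)."""
    path = Path(path)
    meta = {"sample": path.stem, "role": "sample", "polarity": "negative"}
    n_scans = None
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, val = line[1:].partition(":")
            key, val = key.strip(), val.strip()
            if key in meta:
                meta[key] = val
            elif key == "n_scans":
                n_scans = int(val)
        else:
            body_start = i
            break
    df = pd.read_csv(_io.StringIO("".join(lines[body_start:])), float_precision="round_trip")
    expected = ["scan_index", "rt_min", "mz", "intensity"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: malformed scan table, columns {list(df.columns)}")
    if df.isna().any().any():
        raise ValueError(f"{path}: truncated or malformed rows")
    scans = []
    for idx, grp in df.groupby("scan_index", sort=True):
        rt = float(grp["rt_min"].iloc[0])
        scans.append(
            Scan(
                rt=rt,
                mz=grp["mz"].to_numpy(),
                intensity=grp["intensity"].to_numpy(),
                polarity=meta["polarity"],
            )
        )
    if n_scans is not None and len(scans) != n_scans:
        raise ValueError(f"{path}: expected {n_scans} scans, found {len(scans)}")
    return Run(scans=scans, sample=meta["sample"], role=meta["role"], polarity=meta["polarity"])


def read_run(path: str | Path, role: str = "sample") -> Run:
    """Dispatch on extension: .mzML via pyteomics, .csv scan-table dialect."""
    p = Path(path)
    if p.suffix.lower() == ".mzml":
        return read_mzml(p, role=role)
    if p.suffix.lower() == ".csv":
        return read_scan_table(p)
    raise ValueError(f"unsupported run format: {p.suffix}")


def write_table(path: str | Path, rows: pd.DataFrame) -> None:
    """Write a results table as CSV (the single tabular output format)."""
    rows.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# spectral library I/O (matchms-backed)


def _to_matchms(entry: LibraryEntry):
    from matchms import Spectrum

    meta = {
        "compound_name": entry.name,
        "formula": str(entry.formula),
        "precursor_mz": float(entry.spectrum.precursor_mz),
        "adduct": entry.spectrum.species_label or "",
    }
    if entry.rt is not None:
        meta["retention_time"] = float(entry.rt)
    return Spectrum(
        mz=np.array([m for m, _ in entry.spectrum.fragments], dtype=float),
        intensities=np.array([i for _, i in entry.spectrum.fragments], dtype=float),
        metadata=meta,
        metadata_harmonization=False,
    )


def _from_matchms(spec) -> LibraryEntry:
    meta = spec.metadata
    name = meta.get("compound_name") or meta.get("name") or meta.get("title") or ""
    formula = parse_formula(str(meta["formula"]))
    adduct = meta.get("adduct") or None
    rt = meta.get("retention_time")
    precursor = meta.get("precursor_mz")
    if precursor is None and adduct:
        precursor = ion_mz(formula, ION_SPECIES[adduct])
    ms2 = MS2Spectrum(
        precursor_mz=float(precursor),
        fragments=list(zip(spec.peaks.mz.tolist(), spec.peaks.intensities.tolist())),
        species_label=adduct,
        rt=float(rt) if rt is not None else None,
    )
    return LibraryEntry(name=str(name), formula=formula, spectrum=ms2,
                        rt=float(rt) if rt is not None else None)


def save_library_msp(library: list[LibraryEntry], path: str | Path) -> None:
    from matchms.exporting import save_as_msp

    p = Path(path)
    if p.exists():
        p.unlink()
    save_as_msp([_to_matchms(e) for e in library], str(p))


def load_library_msp(path: str | Path) -> list[LibraryEntry]:
    from matchms.importing import load_from_msp

    return [_from_matchms(s) for s in load_from_msp(str(path), metadata_harmonization=False)]


def save_library_mgf(library: list[LibraryEntry], path: str | Path) -> None:
    from matchms.exporting import save_as_mgf

    p = Path(path)
    if p.exists():
        p.unlink()
    save_as_mgf([_to_matchms(e) for e in library], str(p))


def load_library_mgf(path: str | Path) -> list[LibraryEntry]:
    from matchms.importing import load_from_mgf

    return [_from_matchms(s) for s in load_from_mgf(str(path), metadata_harmonization=False)]
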