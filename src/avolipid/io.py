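"""Readers and writers for every format the pipeline touches.

Scan maps are exchanged as mzML (a minimal, self-contained subset of the
schema: MS1 centroid spectra, 64-bit little-endian uncompressed binary
arrays) and as long-format CSV with columns (scan_time_min, mz,
intensity). CSVs are UTF-8, header row, '.' decimal.
"""

from __future__ import annotations

import base64
import logging
import struct
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import pandas as pd

from . import chem
from .signal import FeatureTable
from .synthetic import GroundTruthLedger, LipidRecord, ScanMap, TissueProfile

logger = logging.getLogger(__name__)

_MZML_NS = "http://psi.hupo.org/ms/mzml"


# --- scan maps: CSV -----------------------------------------------------


def write_scan_map_csv(scan_map: ScanMap, path) -> None:
    """Long-format CSV; empty scans keep a placeholder row so the scan grid
    round-trips exactly."""
    frames = []
    for t, (mz, inten) in zip(scan_map.scan_times, scan_map.scans):
        if mz.size:
            frames.append(
                pd.DataFrame({"scan_time_min": t, "mz": mz, "intensity": inten})
            )
        else:
            frames.append(
                pd.DataFrame({"scan_time_min": [t], "mz": [np.nan], "intensity": [np.nan]})
            )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.8g")


def read_scan_map_csv(path, sample_id: str = "") -> ScanMap:
    df = pd.read_csv(path)
    required = {"scan_time_min", "mz", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    times = []
    scans = []
    for t, sub in df.groupby("scan_time_min", sort=True):
        times.append(float(t))
        sub = sub.dropna(subset=["mz"])
        order = np.argsort(sub["mz"].to_numpy())
        scans.append(
            (sub["mz"].to_numpy(dtype=float)[order], sub["intensity"].to_numpy(dtype=float)[order])
        )
    return ScanMap(np.array(times), scans, sample_id=sample_id or Path(path).stem)


# --- scan maps: mzML ----------------------------------------------------


def _encode_array(values: np.ndarray) -> str:
    raw = struct.pack(f"<{values.size}d", *values.astype(float))
    return base64.b64encode(raw).decode("ascii")


def _decode_array(text: str, n: int) -> np.ndarray:
    raw = base64.b64decode(text)
    return np.array(struct.unpack(f"<{n}d", raw))


def write_scan_map_mzml(scan_map: ScanMap, path) -> None:
    root = ET.Element("mzML", xmlns=_MZML_NS, version="1.1.0")
    run = ET.SubElement(root, "run", id=scan_map.sample_id or "run1")
    spectrum_list = ET.SubElement(run, "spectrumList", count=str(scan_map.n_scans))
    for i, (t, (mz, inten)) in enumerate(zip(scan_map.scan_times, scan_map.scans)):
        spectrum = ET.SubElement(
            spectrum_list, "spectrum", index=str(i), id=f"scan={i + 1}",
            defaultArrayLength=str(mz.size),
        )
        ET.SubElement(
            spectrum, "cvParam", accession="MS:1000511", name="ms level", value="1"
        )
        ET.SubElement(
            spectrum, "cvParam", accession="MS:1000127", name="centroid spectrum", value=""
        )
        scan_el = ET.SubElement(ET.SubElement(spectrum, "scanList"), "scan")
        ET.SubElement(
            scan_el, "cvParam", accession="MS:1000016", name="scan start time",
            value=f"{t:.17g}", unitName="minute",
        )
        arrays = ET.SubElement(spectrum, "binaryDataArrayList", count="2")
        for accession, name, values in (
            ("MS:1000514", "m/z array", mz),
            ("MS:1000515", "intensity array", inten),
        ):
            array_el = ET.SubElement(arrays, "binaryDataArray")
            ET.SubElement(array_el, "cvParam", accession="MS:1000523", name="64-bit float", value="")
            ET.SubElement(array_el, "cvParam", accession="MS:1000576", name="no compression", value="")
            ET.SubElement(array_el, "cvParam", accession=accession, name=name, value="")
            ET.SubElement(array_el, "binary").text = _encode_array(values)
    ET.indent(root)
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="utf-8")


def read_scan_map_mzml(path, sample_id: str = "") -> ScanMap:
    def tag(name):
        return f"{{{_MZML_NS}}}{name}"

    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise ValueError(f"{path}: malformed mzML ({exc})") from exc
    times = []
    scans = []
    for spectrum in tree.iter(tag("spectrum")):
        params = {p.get("accession"): p.get("value") for p in spectrum.iter(tag("cvParam"))}
        ms_level = params.get("MS:1000511", "1")
        if ms_level != "1":
            logger.warning(
                "%s: ignoring MS%s spectrum %s", path, ms_level, spectrum.get("id")
            )
            continue
        if "MS:1000016" not in params:
            raise ValueError(f"{path}: spectrum {spectrum.get('id')} lacks a scan start time")
        n = int(spectrum.get("defaultArrayLength", "0"))
        mz = inten = np.empty(0)
        for array_el in spectrum.iter(tag("binaryDataArray")):
            accs = {p.get("accession") for p in array_el.iter(tag("cvParam"))}
            binary = array_el.find(tag("binary"))
            values = _decode_array(binary.text or "", n) if n else np.empty(0)
            if "MS:1000514" in accs:
                mz = values
            elif "MS:1000515" in accs:
                inten = values
        times.append(float(params["MS:1000016"]))
        scans.append((mz, inten))
    order = np.argsort(times)
    return ScanMap(
        np.array(times)[order],
        [scans[i] for i in order],
        sample_id=sample_id or Path(path).stem,
    )


def read_scan_map(path, sample_id: str = "") -> ScanMap:
    path = Path(path)
    if path.suffix.lower() == ".mzml":
        return read_scan_map_mzml(path, sample_id)
    return read_scan_map_csv(path, sample_id)


# --- lipid DB -----------------------------------------------------------

_DB_COLUMNS = ["record_id", "name", "formula", "mass", "category", "main_class", "subclass", "rt_affinity"]


def write_lipid_db_tsv(db: list[LipidRecord], path) -> None:
    rows = [
        {
            "record_id": r.record_id,
            "name": r.name,
            "formula": r.formula_string,
            "mass": r.monoisotopic_mass,
            "category": r.category,
            "main_class": r.main_class,
            "subclass": r.subclass,
            "rt_affinity": r.rt_affinity,
        }
        for r in db
    ]
    pd.DataFrame(rows, columns=_DB_COLUMNS).to_csv(path, sep="\t", index=False)


def read_lipid_db_tsv(path) -> list[LipidRecord]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    missing = set(_DB_COLUMNS[:-1]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        records.append(
            LipidRecord(
                record_id=row["record_id"],
                name=row["name"],
                formula=chem.parse_formula(row["formula"]),
                monoisotopic_mass=float(row["mass"]),
                category=row["category"],
                main_class=row["main_class"],
                subclass=row["subclass"],
                rt_affinity=float(row.get("rt_affinity", 10.0)),
            )
        )
    return records


# --- profiles, ledger, tables -------------------------------------------


def write_profiles_csv(profiles: list[TissueProfile], path) -> None:
    rows = []
    for p in profiles:
        for analyte, conc in sorted(p.concentrations.items()):
            rows.append(
                {
                    "sample_id": p.sample_id,
                    "tissue": p.tissue,
                    "stage": p.stage,
                    "replicate": p.replicate,
                    "fresh_weight_g": p.fresh_weight,
                    "dw_fraction": p.dw_fraction,
                    "analyte": analyte,
                    "conc_mg_per_gfw": conc,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_ledger_csv(ledger: GroundTruthLedger, path) -> None:
    rows = [
        {
            "sample_id": p.sample_id,
            "analyte": p.analyte,
            "adduct": p.adduct,
            "charge": p.charge,
            "mz": p.mz,
            "rt_center_min": p.rt_center,
            "fwhm_s": p.fwhm_s,
            "apex_intensity": p.apex_intensity,
            "area_counts_s": p.area,
            "isotope_abundances": ";".join(f"{a:.6g}" for a in p.isotope_abundances),
            "dropped": p.dropped,
        }
        for p in ledger.peaks
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_feature_table_csv(table: FeatureTable, path) -> None:
    table.to_dataframe().to_csv(path, index=False, float_format="%.8g")


def read_feature_table_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "feature_id" not in df.columns:
        raise ValueError(f"{path}: missing column 'feature_id'")
    return df


def write_uv_table_csv(areas_by_sample: dict[str, dict[str, float]], path) -> None:
    rows = [
        {"sample_id": sid, "analyte": analyte, "area_220nm": area}
        for sid, areas in areas_by_sample.items()
        for analyte, area in areas.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_uv_table_csv(path) -> dict[str, dict[str, float]]:
    df = pd.read_csv(path)
    required = {"sample_id", "analyte", "area_220nm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    out: dict[str, dict[str, float]] = {}
    for _, row in df.iterrows():
        out.setdefault(row["sample_id"], {})[row["analyte"]] = float(row["area_220nm"])
    return out
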