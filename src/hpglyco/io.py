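"""Readers and writers for the pipeline's interchange formats.

Primary interchange is plain CSV (diffable, desk-scale): the transition
list, per-patient chromatogram fixtures in long format, cohort metadata,
and the results tables. mzML is an optional export/import adapter for the
same chromatogram arrays. Conventions: retention times in minutes, all m/z
monoisotopic, m/z serialized at 4 decimals, 1-based isomer indices.
"""

from __future__ import annotations

import base64
import hashlib
import json
import struct
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence
from xml.sax.saxutils import escape

import numpy as np
import pandas as pd
import yaml

from .glyco_model import (
    SITES,
    GlycopeptideTarget,
    parse_glycan_code,
    precursor_mz,
    quantifier_fragments,
)
from .quant import ChromatogramSet, QuantParams
from .stats_markers import StatsConfig
from .synthetic import CohortConfig, PatientRecord

__all__ = [
    "RunConfig",
    "write_transition_csv",
    "read_transition_csv",
    "write_chromatogram_csv",
    "read_chromatogram_csv",
    "write_cohort_metadata",
    "read_cohort_metadata",
    "write_mzml_chromatograms",
]


class SchemaError(ValueError):
    """A file violated its documented schema (reported with coordinates)."""


TRANSITION_COLUMNS = [
    "site_id",
    "peptide",
    "glycan_code",
    "isomer_index",
    "charge",
    "precursor_mz",
    "fragment_mzs",
    "expected_rt_min",
    "rt_window_min",
]


def write_transition_csv(targets: Sequence[GlycopeptideTarget], path: str | Path) -> None:
    """One row per isomer entry; fragment m/z semicolon-joined at 4 decimals."""
    rows = []
    for t in targets:
        rows.append(
            {
                "site_id": t.site.site_id,
                "peptide": t.site.peptide_sequence,
                "glycan_code": str(t.composition),
                "isomer_index": t.isomer_index,
                "charge": t.charge,
                "precursor_mz": f"{t.precursor_mz:.4f}",
                "fragment_mzs": ";".join(f"{mz:.4f}" for mz in t.fragment_mzs),
                "expected_rt_min": f"{t.expected_rt:.2f}",
                "rt_window_min": f"{t.site.elution_window[0]:.1f}-{t.site.elution_window[1]:.1f}",
            }
        )
    pd.DataFrame(rows, columns=TRANSITION_COLUMNS).to_csv(path, index=False)


def read_transition_csv(path: str | Path) -> list[GlycopeptideTarget]:
    """Read a transition list; masses are recomputed from site + composition
    and validated against the serialized values (1e-3 m/z)."""
    df = pd.read_csv(path, dtype=str)
    missing = set(TRANSITION_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"transition CSV missing columns: {sorted(missing)}")
    counts: dict[tuple[str, str], int] = {}
    for _, row in df.iterrows():
        k = (row["site_id"], row["glycan_code"])
        counts[k] = max(counts.get(k, 0), int(row["isomer_index"]))
    targets = []
    for i, row in df.iterrows():
        site = SITES.get(row["site_id"])
        if site is None:
            raise SchemaError(f"row {i}: unknown site_id {row['site_id']!r}")
        if row["peptide"] != site.peptide_sequence:
            raise SchemaError(f"row {i}, column peptide: {row['peptide']!r} does not match {site.site_id}")
        comp = parse_glycan_code(row["glycan_code"])
        charge = int(row["charge"])
        mz = precursor_mz(site, comp, charge)
        if abs(mz - float(row["precursor_mz"])) > 1e-3:
            raise SchemaError(
                f"row {i}, column precursor_mz: {row['precursor_mz']} "
                f"inconsistent with computed {mz:.4f}"
            )
        targets.append(
            GlycopeptideTarget(
                site=site,
                composition=comp,
                charge=charge,
                precursor_mz=mz,
                fragment_mzs=quantifier_fragments(site, comp),
                expected_rt=float(row["expected_rt_min"]),
                isomer_index=int(row["isomer_index"]),
                n_isomers=counts[(row["site_id"], row["glycan_code"])],
            )
        )
    return targets


def write_chromatogram_csv(chromset: ChromatogramSet, path: str | Path) -> None:
    """Long-format fixture: time_min, fragment_mz, intensity, target_key."""
    frames = []
    for (key, mz), intensity in chromset.traces.items():
        frames.append(
            pd.DataFrame(
                {
                    "time_min": chromset.time,
                    "fragment_mz": f"{mz:.4f}",
                    "intensity": intensity,
                    "target_key": key,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_chromatogram_csv(path: str | Path) -> ChromatogramSet:
    df = pd.read_csv(path)
    required = {"time_min", "fragment_mz", "intensity", "target_key"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    bad = df.index[df["intensity"] < 0]
    if len(bad):
        raise SchemaError(f"{path}: negative intensity at row {bad[0]}, column intensity")
    traces: dict[tuple[str, float], np.ndarray] = {}
    time = None
    for (key, mz), sub in df.groupby(["target_key", "fragment_mz"], sort=False):
        t = sub["time_min"].to_numpy(dtype=float)
        if time is None:
            time = t
        elif len(t) != len(time) or not np.allclose(t, time):
            raise SchemaError(f"{path}: trace ({key}, {mz}) is not on the shared time grid")
        traces[(str(key), float(mz))] = sub["intensity"].to_numpy(dtype=float)
    if time is None:
        raise SchemaError(f"{path}: no traces found")
    return ChromatogramSet(time=time, traces=traces)


def write_cohort_metadata(patients: Sequence[PatientRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "group": p.group,
                "gender": p.gender,
                "afp_ng_ml": p.afp_ng_ml,
                "tnm_stage": p.tnm_stage,
            }
            for p in patients
        ]
    ).to_csv(path, index=False)


def read_cohort_metadata(path: str | Path) -> list[PatientRecord]:
    df = pd.read_csv(path, keep_default_na=False)  # "NA" is a literal stage value
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                PatientRecord(
                    patient_id=str(row["patient_id"]),
                    group=str(row["group"]),
                    gender=str(row["gender"]),
                    afp_ng_ml=float(row["afp_ng_ml"]),
                    tnm_stage=str(row["tnm_stage"]),
                )
            )
        except (KeyError, ValueError) as exc:
            raise SchemaError(f"{path}: row {i}: {exc}") from exc
    return out


# --- optional mzML adapter -------------------------------------------------

def _encode_array(values: np.ndarray) -> str:
    raw = struct.pack(f"<{len(values)}d", *np.asarray(values, dtype=float))
    return base64.b64encode(raw).decode("ascii")


def write_mzml_chromatograms(chromset: ChromatogramSet, path: str | Path) -> None:
    """Export the fixture traces as an mzML chromatogram list.

    Minimal, uncompressed (64-bit little-endian) mzML 1.1 output; each trace
    becomes one chromatogram with id ``"<target_key>|<fragment m/z>"``, time
    in minutes. Readable by standard mzML parsers.
    """
    chroms = []
    for idx, ((key, mz), intensity) in enumerate(chromset.traces.items()):
        cid = escape(f"{key}|{mz:.4f}")
        time_b64 = _encode_array(chromset.time)
        int_b64 = _encode_array(intensity)
        n = len(chromset.time)
        chroms.append(f"""
      <chromatogram index="{idx}" id="{cid}" defaultArrayLength="{n}">
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{len(time_b64)}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000595" name="time array" value="" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>
            <binary>{time_b64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{len(int_b64)}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
            <binary>{int_b64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </chromatogram>""")
    body = "".join(chroms)
    doc = f"""<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="2">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="UO" fullName="Unit Ontology" URI="http://obo.cvs.sourceforge.net/obo/obo/ontology/phenotype/unit.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000810" name="ion current chromatogram" value=""/>
    </fileContent>
  </fileDescription>
  <softwareList count="1">
    <software id="hpglyco" version="0.1.0"/>
  </softwareList>
  <instrumentConfigurationList count="1">
    <instrumentConfiguration id="IC1"/>
  </instrumentConfigurationList>
  <dataProcessingList count="1">
    <dataProcessing id="export">
      <processingMethod order="1" softwareRef="hpglyco">
        <cvParam cvRef="MS" accession="MS:1000544" name="Conversion to mzML" value=""/>
      </processingMethod>
    </dataProcessing>
  </dataProcessingList>
  <run id="run1" defaultInstrumentConfigurationRef="IC1">
    <chromatogramList count="{len(chromset.traces)}" defaultDataProcessingRef="export">{body}
    </chromatogramList>
  </run>
</mzML>
"""
    Path(path).write_text(doc)


def read_mzml_chromatograms(path: str | Path) -> ChromatogramSet:
    """Import a chromatogram-list mzML written by the export adapter.

    Expects uncompressed 64-bit float arrays and chromatogram ids of the
    form ``"<target_key>|<fragment m/z>"``.
    """
    import xml.etree.ElementTree as ET

    ns = {"mz": "http://psi.hupo.org/ms/mzml"}
    root = ET.parse(path).getroot()
    traces: dict[tuple[str, float], np.ndarray] = {}
    time = None
    for chrom in root.iter("{http://psi.hupo.org/ms/mzml}chromatogram"):
        cid = chrom.attrib["id"]
        arrays: dict[str, np.ndarray] = {}
        for bda in chrom.iterfind(".//mz:binaryDataArray", ns):
            names = {cv.attrib["name"] for cv in bda.iterfind("mz:cvParam", ns)}
            binary = bda.find("mz:binary", ns)
            raw = base64.b64decode(binary.text or "")
            values = np.frombuffer(raw, dtype="<f8")
            if "time array" in names:
                arrays["time"] = values
            elif "intensity array" in names:
                arrays["intensity"] = values
        if "time" not in arrays or "intensity" not in arrays:
            raise SchemaError(f"{path}: chromatogram {cid!r} lacks time/intensity arrays")
        if time is None:
            time = arrays["time"]
        key, _, mz = cid.rpartition("|")
        traces[(key, float(mz))] = arrays["intensity"]
    if time is None:
        raise SchemaError(f"{path}: no chromatograms found")
    return ChromatogramSet(time=np.array(time), traces=traces)


# --- run configuration ----------------------------------------------------

@dataclass
class RunConfig:
    """One reproducible pipeline run: paths, sub-configs, seed, provenance."""

    output_dir: str = "results"
    targets_csv: str | None = None
    chromatogram_dir: str | None = None
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    quant: QuantParams = field(default_factory=QuantParams)
    stats: StatsConfig = field(default_factory=StatsConfig)
    log_level: str = "INFO"
    #: acquisition metadata carried as provenance only
    collision_energy_ev: float = 25.0
    gradient: str = "100 min, 2-38-60-90% B on 50 cm C18 at 60 C"

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cohort = raw.pop("cohort", {})
        peaks = cohort.pop("peaks", {})
        quant = raw.pop("quant", {})
        stats = raw.pop("stats", {})

        def _tupled(d: dict) -> dict:
            return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}

        cohort = _tupled(cohort)
        for key in ("gender_counts", "afp_median", "class_means", "target_overrides"):
            if key in cohort and isinstance(cohort[key], dict):
                cohort[key] = {
                    k: tuple(v) if isinstance(v, list) else v for k, v in cohort[key].items()
                }
        if "class_means" in cohort:
            cohort["class_means"] = {
                site: {g: tuple(m) for g, m in by_group.items()}
                for site, by_group in cohort["class_means"].items()
            }
        cfg = cls(
            cohort=CohortConfig(**cohort, peaks=PeakModelFromDict(peaks)),
            quant=QuantParams(**_tupled(quant)),
            stats=StatsConfig(**stats),
            **raw,
        )
        return cfg

    def manifest(self) -> dict:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return {
            "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
            "seed": self.seed,
            "package": "hpglyco 0.1.0",
            "numpy": np.__version__,
            "pandas": pd.__version__,
        }


def PeakModelFromDict(d: Mapping) -> "PeakModel":
    from .synthetic import PeakModel

    d = {k: tuple(v) if isinstance(v, list) else v for k, v in dict(d).items()}
    return PeakModel(**d)
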