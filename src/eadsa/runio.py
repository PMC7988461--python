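"""Serialization of simulated runs and peak tables.

Formats:

* ``peak_table_csv`` — pre-integrated areas per species/fraction (what the
  quantification layer consumes when spectra are not needed); lossless
  round trip.
* ``centroid_jsonl`` — one JSON object per line: a header with metadata and
  the ground-truth ledger, then one line per scan; lossless round trip.
* ``mzml`` — minimal write-only mzML export for interoperability with
  standard mass-spectrometry readers.
"""

from __future__ import annotations

import base64
import json
import struct
import zlib
from dataclasses import asdict
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .registry import Fraction, GP_FOR_FRACTION, Registry, build_default_registry, derivative_ion
from .simulate import GroundTruth, InstrumentModel, Scan, SimulatedRun

PEAK_TABLE_COLUMNS = [
    "run_id", "species_id", "fraction", "gp", "mz_channel",
    "rt_min", "area", "conformer_index", "flags",
]


def peak_table(run: SimulatedRun, run_id: str = "run",
               registry: Optional[Registry] = None) -> pd.DataFrame:
    """Ground-truth-derived peak table (bypasses signal extraction)."""
    registry = registry or build_default_registry()
    inst = run.instrument
    rows = []
    splits = [inst.conformer_split]
    if inst.conformer_split < 1.0:
        splits.append(1.0 - inst.conformer_split)
    for sid, fracs in sorted(run.ground_truth.fraction_amounts_ng.items()):
        sp = registry.lookup(sid)
        for fraction in ("A", "B"):
            ng = fracs.get(fraction, 0.0)
            if ng <= 0:
                continue
            gp = GP_FOR_FRACTION[Fraction(fraction)]
            ion = derivative_ion(sp, fraction, gp)
            rt = sp.nominal_rt_min + (
                inst.rt_shift_labeled_min if sp.label_count else 0.0
            )
            area = ng * inst.area_per_ng * inst.rf(sid)
            for ci, split in enumerate(splits):
                rows.append({
                    "run_id": run_id,
                    "species_id": sid,
                    "fraction": fraction,
                    "gp": gp.label,
                    "mz_channel": round(ion.mz, 4),
                    "rt_min": round(rt + ci * inst.conformer_rt_gap_min, 3),
                    "area": area * split,
                    "conformer_index": ci,
                    "flags": "",
                })
    return pd.DataFrame(rows, columns=PEAK_TABLE_COLUMNS)


def write_run(run: SimulatedRun, path, format: str = "centroid_jsonl",
              run_id: str = "run") -> None:
    if format == "peak_table_csv":
        peak_table(run, run_id).to_csv(path, index=False)
    elif format == "centroid_jsonl":
        _write_jsonl(run, path)
    elif format == "mzml":
        _write_mzml(run, path)
    else:
        raise ValueError(f"unknown run format: {format}")


def read_peak_table(path) -> pd.DataFrame:
    return pd.read_csv(path, keep_default_na=False, dtype={"flags": str})


# ---------------------------------------------------------------------------
# centroid JSONL
# ---------------------------------------------------------------------------

def _write_jsonl(run: SimulatedRun, path) -> None:
    header = {
        "kind": "eadsa_centroid_run",
        "seed": run.seed,
        "instrument": asdict(run.instrument),
        "ground_truth": asdict(run.ground_truth),
    }
    with open(path, "w") as fh:
        fh.write(json.dumps(header, sort_keys=True) + "\n")
        for s in run.scans:
            rec = {
                "t": round(s.time_min, 6),
                "level": s.ms_level,
                "prec": [round(p, 4) for p in s.precursors],
                "mz": [round(float(m), 6) for m in s.mz],
                "i": [round(float(v), 6) for v in s.intensity],
            }
            fh.write(json.dumps(rec) + "\n")


def read_run(path) -> SimulatedRun:
    """Read a ``centroid_jsonl`` run back into memory."""
    with open(path) as fh:
        header = json.loads(fh.readline())
        if header.get("kind") != "eadsa_centroid_run":
            raise ValueError("not a centroid_jsonl run file")
        scans = []
        for line in fh:
            rec = json.loads(line)
            scans.append(Scan(
                rec["t"], rec["level"], tuple(rec["prec"]),
                np.asarray(rec["mz"], dtype=float),
                np.asarray(rec["i"], dtype=float),
            ))
    gt = GroundTruth(**header["ground_truth"])
    inst = InstrumentModel(**header["instrument"])
    return SimulatedRun(scans, gt, header["seed"], inst)


# ---------------------------------------------------------------------------
# minimal mzML (write-only)
# ---------------------------------------------------------------------------

def _b64(values: np.ndarray) -> str:
    raw = struct.pack(f"<{len(values)}d", *values)
    return base64.b64encode(zlib.compress(raw)).decode()


def _write_mzml(run: SimulatedRun, path) -> None:
    spectra = []
    for idx, s in enumerate(run.scans):
        mz64, i64 = _b64(np.asarray(s.mz, float)), _b64(np.asarray(s.intensity, float))
        prec = ""
        if s.ms_level > 1 and s.precursors:
            sel = "".join(
                f'<precursor><selectedIonList count="1"><selectedIon>'
                f'<cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" value="{p:.4f}"/>'
                f"</selectedIon></selectedIonList></precursor>"
                for p in s.precursors
            )
            prec = f'<precursorList count="{len(s.precursors)}">{sel}</precursorList>'
        spectra.append(f"""
  <spectrum index="{idx}" id="scan={idx}" defaultArrayLength="{len(s.mz)}">
   <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{s.ms_level}"/>
   <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
   <scanList count="1"><scan>
    <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{s.time_min:.6f}" unitName="minute"/>
   </scan></scanList>{prec}
   <binaryDataArrayList count="2">
    <binaryDataArray encodedLength="{len(mz64)}">
     <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
     <cvParam cvRef="MS" accession="MS:1000574" name="zlib compression" value=""/>
     <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitName="m/z"/>
     <binary>{mz64}</binary>
    </binaryDataArray>
    <binaryDataArray encodedLength="{len(i64)}">
     <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
     <cvParam cvRef="MS" accession="MS:1000574" name="zlib compression" value=""/>
     <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitName="number of detector counts"/>
     <binary>{i64}</binary>
    </binaryDataArray>
   </binaryDataArrayList>
  </spectrum>""")
    doc = f"""<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
 <cvList count="1">
  <cv id="MS" fullName="PSI-MS" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
 </cvList>
 <run id="eadsa_run">
 <spectrumList count="{len(run.scans)}" defaultDataProcessingRef="dp">
{''.join(spectra)}
 </spectrumList>
 </run>
</mzML>
"""
    with open(path, "w") as fh:
        fh.write(doc)
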