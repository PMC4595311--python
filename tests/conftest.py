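"""Shared fixtures: small hand-made peak lists, datasets on disk, and a
programmatically generated minimal mzML file."""

from __future__ import annotations

import base64
import struct
from pathlib import Path

import numpy as np
import pytest

from maldikd.preprocess import PeakList
from maldikd.matching import PeakMatrix
from maldikd.spectra_io import Spectrum


def make_peaklist(spectrum_id, mz, intensity=None):
    mz = np.asarray(mz, dtype=float)
    if intensity is None:
        intensity = np.ones_like(mz)
    return PeakList(spectrum_id, mz, np.asarray(intensity, dtype=float))


def make_spectrum(intensity, mz=None, sid="s", sample="sample", rep=0):
    intensity = np.asarray(intensity, dtype=float)
    if mz is None:
        mz = np.arange(len(intensity), dtype=float) + 1.0
    return Spectrum(sid, sample, rep, np.asarray(mz, dtype=float), intensity)


def make_matrix(values, sample_ids=None, conditions=None, mz=None, mode="binary"):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    sample_ids = sample_ids or [f"s{i}" for i in range(n)]
    conditions = conditions or ["A"] * n
    mz = mz if mz is not None else 100.0 * (np.arange(p) + 1)
    return PeakMatrix(sample_ids, conditions, np.asarray(mz, float), values, mode)


MZML_TEMPLATE = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="1">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology"
        URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
    </fileContent>
  </fileDescription>
  <run id="run1">
    <spectrumList count="{count}">
{spectra}
    </spectrumList>
  </run>
</mzML>
"""

MZML_SPECTRUM = """      <spectrum index="{index}" id="scan={index}" defaultArrayLength="{length}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{ms_level}"/>
        <cvParam cvRef="MS" accession="MS:1000128" name="profile spectrum" value=""/>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{mz_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>
            <binary>{mz_b64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{int_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>
            <binary>{int_b64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>"""


def _b64_doubles(values):
    return base64.b64encode(struct.pack(f"<{len(values)}d", *values)).decode()


def write_mzml(path: Path, spectra: list[tuple[list[float], list[float]]],
               ms_levels: list[int] | None = None) -> Path:
    """Write a minimal mzML 1.1 document with the given (mz, intensity) scans."""
    ms_levels = ms_levels or [1] * len(spectra)
    blocks = []
    for i, ((mz, intensity), level) in enumerate(zip(spectra, ms_levels)):
        mz_b64 = _b64_doubles(mz)
        int_b64 = _b64_doubles(intensity)
        blocks.append(MZML_SPECTRUM.format(
            index=i, length=len(mz), ms_level=level,
            mz_len=len(mz_b64), mz_b64=mz_b64,
            int_len=len(int_b64), int_b64=int_b64,
        ))
    path.write_text(MZML_TEMPLATE.format(count=len(spectra), spectra="\n".join(blocks)))
    return path


@pytest.fixture
def tiny_dataset_dir(tmp_path):
    """condition_dirs layout: A/{s1:[r1,r2], s2:[r1]}, B/{s3:[r1]}."""
    specs = {
        ("A", "s1", "r1"): ([100.0, 200.0, 300.0], [1.0, 2.0, 3.0]),
        ("A", "s1", "r2"): ([100.0, 200.0, 300.0], [1.5, 2.5, 3.5]),
        ("A", "s2", "r1"): ([100.0, 250.0], [1.0, 1.0]),
        ("B", "s3", "r1"): ([110.0, 210.0], [4.0, 5.0]),
    }
    for (cond, sample, rep), (mz, inten) in specs.items():
        d = tmp_path / cond / sample
        d.mkdir(parents=True, exist_ok=True)
        lines = ["mz,intensity"] + [f"{m},{i}" for m, i in zip(mz, inten)]
        (d / f"{rep}.csv").write_text("\n".join(lines) + "\n")
    return tmp_path
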