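"""ECG visit records and the XML dialect they are stored in.

One record corresponds to one ECG collection visit: subject metadata
(encoded id, birth date, sex, weight, height), the lead-I waveform
(5000 samples at 500 Hz, stored as whitespace-separated integers in
microvolts), the collection datetime and the cardiologist's free-text
report.  The dialect is deliberately minimal::

    <ecg_record>
      <subject_id>GX-000123</subject_id>
      <birth_date>2005-06-01</birth_date>
      <collection_datetime>2015-07-15T10:30:00</collection_datetime>
      <sex>female</sex>
      <weight_kg>45.2</weight_kg>
      <height_cm>142.0</height_cm>
      <report>normal</report>
      <waveform lead="I" sampling_rate_hz="500" units="uV">12 -5 938 ...</waveform>
    </ecg_record>

Amplitudes are integer microvolts (1 unit = 1 uV); the in-memory
``signal`` array uses the same scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path

import numpy as np
from lxml import etree

SAMPLING_RATE_HZ = 500
RECORD_DURATION_S = 10
RECORD_LENGTH = SAMPLING_RATE_HZ * RECORD_DURATION_S  # 5000 samples


class SchemaError(ValueError):
    """A mandatory element is missing from an XML record."""

    def __init__(self, element: str, path: str | None = None):
        self.element = element
        super().__init__(f"missing mandatory element '{element}'"
                         + (f" in {path}" if path else ""))


@dataclass
class ECGRecord:
    """One subject visit: metadata plus the lead-I waveform."""

    subject_id: str
    birth_date: date
    collection_date: datetime
    sex: str                      # "male" | "female"
    weight_kg: float
    height_cm: float
    signal: np.ndarray            # integer microvolts
    report_text: str = "normal"
    source_path: str | None = None
    # Generator-only ground truth (R-peak sample indices); never serialised
    # into the XML record, only into the cohort manifest.
    r_truth: np.ndarray | None = None

    @property
    def height_m(self) -> float:
        return self.height_cm / 100.0

    def signal_mv(self) -> np.ndarray:
        """Waveform in millivolts as float64."""
        return np.asarray(self.signal, dtype=np.float64) / 1000.0


_MANDATORY = ("subject_id", "birth_date", "collection_datetime", "sex",
              "weight_kg", "height_cm", "report", "waveform")


def record_to_xml(record: ECGRecord) -> bytes:
    root = etree.Element("ecg_record")
    etree.SubElement(root, "subject_id").text = record.subject_id
    etree.SubElement(root, "birth_date").text = record.birth_date.isoformat()
    etree.SubElement(root, "collection_datetime").text = (
        record.collection_date.isoformat())
    etree.SubElement(root, "sex").text = record.sex
    etree.SubElement(root, "weight_kg").text = repr(float(record.weight_kg))
    etree.SubElement(root, "height_cm").text = repr(float(record.height_cm))
    etree.SubElement(root, "report").text = record.report_text
    wf = etree.SubElement(root, "waveform", lead="I",
                          sampling_rate_hz=str(SAMPLING_RATE_HZ), units="uV")
    wf.text = " ".join(str(int(v)) for v in np.asarray(record.signal).ravel())
    return etree.tostring(root, pretty_print=True,
                          xml_declaration=True, encoding="UTF-8")


def write_record(record: ECGRecord, path: str | Path) -> None:
    Path(path).write_bytes(record_to_xml(record))


def parse_record(path: str | Path) -> ECGRecord:
    """Parse one XML record; raises ``SchemaError`` naming the first
    missing mandatory element and ``etree.XMLSyntaxError`` on malformed XML.

    An empty ``<waveform>`` element parses successfully into an empty
    signal array; classifying that as missing-signal is the validator's
    job, not the parser's.
    """
    path = Path(path)
    tree = etree.parse(str(path))
    root = tree.getroot()
    found = {}
    for name in _MANDATORY:
        el = root.find(name)
        if el is None:
            raise SchemaError(name, str(path))
        found[name] = el
    text = found["waveform"].text
    signal = (np.array(text.split(), dtype=np.int64)
              if text and text.strip() else np.empty(0, dtype=np.int64))
    return ECGRecord(
        subject_id=found["subject_id"].text.strip(),
        birth_date=date.fromisoformat(found["birth_date"].text.strip()),
        collection_date=datetime.fromisoformat(
            found["collection_datetime"].text.strip()),
        sex=found["sex"].text.strip(),
        weight_kg=float(found["weight_kg"].text),
        height_cm=float(found["height_cm"].text),
        signal=signal,
        report_text=(found["report"].text or "").strip(),
        source_path=str(path),
    )
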