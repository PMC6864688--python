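"""Readers and writers: WFDB records, CSV tables, run manifests.

The WFDB support is a deliberately small subset of the format family,
written here because the full toolkit is not a dependency of this
package: text headers (``.hea``), signal files in formats 212 (packed
12-bit pairs, the MIT-BIH layout) and 16 (little-endian int16), and
MIT-format annotation files.  A writer for the same subset exists so
synthetic records can be round-tripped in tests; nothing beyond what
the heartbeat pipeline needs is implemented.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .ensemble import EvidenceMatrix
from .features import BeatRepresentation, BeatSeries

__all__ = [
    "ANNOTATION_CODES",
    "BEAT_SYMBOLS",
    "read_wfdb",
    "write_wfdb",
    "read_feature_matrix",
    "write_feature_table",
    "read_feature_table",
    "write_partition",
    "read_partition",
    "write_evidence",
    "read_evidence",
    "RunManifest",
]

# MIT annotation code <-> symbol (the subset relevant to beat processing)
ANNOTATION_CODES = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A", 9: "S",
    10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|", 18: "s", 19: "T",
    20: "*", 21: "D", 22: '"', 23: "=", 24: "p", 25: "B", 26: "^", 27: "t",
    28: "+", 29: "u", 30: "?", 31: "!", 32: "[", 33: "]", 34: "e", 35: "n",
    36: "@", 37: "x", 38: "f", 39: "(", 40: ")", 41: "r",
}
_SYMBOL_TO_CODE = {s: c for c, s in ANNOTATION_CODES.items()}

# Annotations that mark beats (rhythm changes, noise marks etc. are
# filtered out before clustering).  '!' (ventricular flutter wave) is
# included because whole-record processing keeps flutter episodes.
BEAT_SYMBOLS = frozenset(
    ["N", "L", "R", "B", "A", "a", "J", "S", "V", "r", "F", "e", "j",
     "n", "E", "/", "f", "Q", "?", "!"]
)


# ---------------------------------------------------------------- WFDB

def _parse_header(hea_path: Path):
    lines = [ln.strip() for ln in hea_path.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    head = lines[0].split()
    record, n_sig = head[0], int(head[1])
    fs = float(head[2]) if len(head) > 2 else 250.0
    n_samples = int(head[3]) if len(head) > 3 else None
    signals = []
    for ln in lines[1:1 + n_sig]:
        tok = ln.split()
        fname, fmt = tok[0], tok[1]
        fmt = int(re.match(r"\d+", fmt).group())  # strip xN/:N/+N modifiers
        gain, baseline, units = 200.0, None, "mV"
        if len(tok) > 2:
            m = re.match(r"(-?[\d.]+)(?:\(([-\d]+)\))?(?:/(\S+))?", tok[2])
            if m:
                gain = float(m.group(1)) or 200.0
                baseline = int(m.group(2)) if m.group(2) else None
                units = m.group(3) or "mV"
        adc_zero = int(tok[4]) if len(tok) > 4 else 0
        if baseline is None:
            baseline = adc_zero
        name = tok[8] if len(tok) > 8 else f"sig{len(signals)}"
        signals.append(dict(file=fname, fmt=fmt, gain=gain, baseline=baseline,
                            units=units, name=name))
    return record, n_sig, fs, n_samples, signals


def _decode_212(raw: np.ndarray, n_values: int) -> np.ndarray:
    raw = raw[: (len(raw) // 3) * 3].reshape(-1, 3).astype(np.int32)
    s0 = raw[:, 0] | ((raw[:, 1] & 0x0F) << 8)
    s1 = raw[:, 2] | ((raw[:, 1] & 0xF0) << 4)
    out = np.empty(2 * len(raw), dtype=np.int32)
    out[0::2], out[1::2] = s0, s1
    out[out > 2047] -= 4096
    return out[:n_values]


def _encode_212(values: np.ndarray) -> bytes:
    v = np.asarray(values, dtype=np.int32)
    if v.size % 2:
        v = np.append(v, 0)
    v = np.where(v < 0, v + 4096, v)
    pairs = v.reshape(-1, 2)
    out = np.empty((len(pairs), 3), dtype=np.uint8)
    out[:, 0] = pairs[:, 0] & 0xFF
    out[:, 1] = ((pairs[:, 0] >> 8) & 0x0F) | (((pairs[:, 1] >> 8) & 0x0F) << 4)
    out[:, 2] = pairs[:, 1] & 0xFF
    return out.tobytes()


def _read_annotations(path: Path) -> tuple[np.ndarray, list[str]]:
    data = np.frombuffer(path.read_bytes(), dtype="<u2")
    samples, symbols = [], []
    t, i = 0, 0
    while i < len(data):
        word = int(data[i]); i += 1
        code, interval = word >> 10, word & 0x3FF
        if code == 0 and interval == 0:          # EOF
            break
        if code == 59:                            # SKIP: 4-byte interval follows
            if interval == 0:
                high, low = int(data[i]), int(data[i + 1]); i += 2
                t += np.int32((high << 16) | low)
            continue
        if code == 63:                            # AUX: skip payload
            i += (interval + 1) // 2
            continue
        if code in (60, 61, 62):                  # NUM / SUB / CHN modifiers
            continue
        t += interval
        samples.append(t)
        symbols.append(ANNOTATION_CODES.get(code, "?"))
    return np.asarray(samples, dtype=np.int64), symbols


def _write_annotations(path: Path, samples: np.ndarray, symbols: list[str]) -> None:
    words: list[int] = []
    prev = 0
    for s, sym in zip(np.asarray(samples, dtype=np.int64), symbols):
        code = _SYMBOL_TO_CODE.get(sym, _SYMBOL_TO_CODE["Q"])
        interval = int(s - prev)
        prev = int(s)
        if interval > 1023:
            words += [59 << 10, (interval >> 16) & 0xFFFF, interval & 0xFFFF,
                      code << 10]
        else:
            words.append((code << 10) | interval)
    words.append(0)  # EOF
    path.write_bytes(np.asarray(words, dtype="<u2").tobytes())


def read_wfdb(record_path, annotation: str = "atr",
              leads: list[str] | None = None,
              beat_symbols: frozenset = BEAT_SYMBOLS) -> BeatSeries:
    """Load a WFDB record plus beat annotations as a :class:`BeatSeries`.

    ``record_path`` is the path without extension.  ``leads`` selects a
    subset of signals by header name; asking for an absent lead raises.
    Non-beat annotations are filtered by ``beat_symbols``.
    """
    record_path = Path(record_path)
    _, n_sig, fs, n_samples, signals = _parse_header(record_path.with_suffix(".hea"))
    dat_path = record_path.parent / signals[0]["file"]
    fmt = signals[0]["fmt"]
    raw = dat_path.read_bytes()
    if fmt == 212:
        flat = _decode_212(np.frombuffer(raw, dtype=np.uint8),
                           (n_samples or (2 * len(raw) // 3 // n_sig) * n_sig) * n_sig)
    elif fmt == 16:
        flat = np.frombuffer(raw, dtype="<i2").astype(np.int32)
        if n_samples:
            flat = flat[: n_samples * n_sig]
    else:
        raise ValueError(f"unsupported WFDB signal format {fmt}")
    digital = flat.reshape(-1, n_sig)
    physical = np.column_stack([
        (digital[:, j] - sig["baseline"]) / sig["gain"]
        for j, sig in enumerate(signals)
    ])
    names = [sig["name"] for sig in signals]
    if leads is not None:
        missing = [l for l in leads if l not in names]
        if missing:
            raise ValueError(f"lead(s) {missing} not present in record "
                             f"{record_path.name} (has {names})")
        cols = [names.index(l) for l in leads]
        physical, names = physical[:, cols], list(leads)

    ann_path = record_path.with_suffix("." + annotation)
    samples, symbols = _read_annotations(ann_path)
    keep = [i for i, s in enumerate(symbols) if s in beat_symbols]
    beat_times = samples[keep] / fs
    kept_symbols = [symbols[i] for i in keep]
    return BeatSeries(signals=physical, fs=fs, beat_times=beat_times,
                      beat_symbols=kept_symbols, lead_names=names)


def write_wfdb(record_path, series: BeatSeries, fmt: int = 16,
               gain: float = 200.0, annotation: str = "atr") -> None:
    """Write a BeatSeries as a WFDB record (header, signal, annotations)."""
    record_path = Path(record_path)
    record_path.parent.mkdir(parents=True, exist_ok=True)
    n_samples, d = series.signals.shape
    digital = np.round(series.signals * gain).astype(np.int32)
    if fmt == 212:
        if np.any(np.abs(digital) > 2047):
            raise ValueError("signal exceeds 12-bit range for format 212")
        payload = _encode_212(digital.reshape(-1))
    elif fmt == 16:
        payload = digital.astype("<i2").tobytes()
    else:
        raise ValueError(f"unsupported WFDB signal format {fmt}")
    (record_path.parent / (record_path.name + ".dat")).write_bytes(payload)

    names = series.lead_names or [f"lead{r}" for r in range(d)]
    lines = [f"{record_path.name} {d} {series.fs:g} {n_samples}"]
    for r in range(d):
        first = int(digital[0, r]) if n_samples else 0
        lines.append(f"{record_path.name}.dat {fmt} {gain:g}(0)/mV 12 0 "
                     f"{first} 0 0 {names[r]}")
    record_path.with_suffix(".hea").write_text("\n".join(lines) + "\n")

    samples = np.round(series.beat_times * series.fs).astype(np.int64)
    symbols = series.beat_symbols or ["N"] * len(samples)
    _write_annotations(record_path.with_suffix("." + annotation), samples, symbols)


# ----------------------------------------------------------- CSV tables

def read_feature_matrix(path) -> tuple[list, np.ndarray]:
    """Generic delimited feature matrix with an id column; returns (ids, X)."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("feature matrix needs an id column plus features")
    ids = df.iloc[:, 0].tolist()
    X = df.iloc[:, 1:].to_numpy(dtype=float)
    if np.any(~np.isfinite(X)):
        raise ValueError("feature matrix contains missing or non-finite values")
    return ids, X


def write_feature_table(path, rep: BeatRepresentation) -> None:
    """Long-format CSV: one row per (beat, lead) with c0..c{N-1}, sigma, R1, R2."""
    n_coef = rep.lead_features[0].shape[1] - 1
    rows = []
    for r, F in enumerate(rep.lead_features):
        for i in range(rep.n_beats):
            row = {"id": i, "lead": r}
            row.update({f"c{j}": F[i, j] for j in range(n_coef)})
            row["sigma"] = F[i, -1]
            row["R1"], row["R2"] = rep.rr[i]
            row["symbol"] = rep.symbols[i] if rep.symbols else ""
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_feature_table(path) -> BeatRepresentation:
    df = pd.read_csv(path, keep_default_na=False)
    required = {"id", "lead", "sigma", "R1", "R2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"feature table missing column(s): {sorted(missing)}")
    coef_cols = sorted((c for c in df.columns if re.fullmatch(r"c\d+", c)),
                       key=lambda c: int(c[1:]))
    leads = sorted(df["lead"].unique())
    blocks, rr, symbols = [], None, None
    for r in leads:
        sub = df[df["lead"] == r].sort_values("id")
        blocks.append(sub[coef_cols + ["sigma"]].to_numpy(dtype=float))
        if rr is None:
            rr = sub[["R1", "R2"]].to_numpy(dtype=float)
            if "symbol" in sub.columns:
                symbols = [str(s) for s in sub["symbol"]]
                if all(s == "" for s in symbols):
                    symbols = None
    return BeatRepresentation(lead_features=blocks, rr=rr, symbols=symbols)


def write_partition(path, labels, ids=None) -> None:
    labels = np.asarray(labels)
    ids = list(range(len(labels))) if ids is None else list(ids)
    pd.DataFrame({"id": ids, "cluster": labels}).to_csv(path, index=False)


def read_partition(path) -> tuple[list, np.ndarray]:
    df = pd.read_csv(path)
    if not {"id", "cluster"} <= set(df.columns):
        raise ValueError("partition file needs 'id' and 'cluster' columns")
    return df["id"].tolist(), df["cluster"].to_numpy()


def write_evidence(path, G: EvidenceMatrix) -> None:
    header = f"# kind={G.kind}"
    with open(path, "w") as fh:
        fh.write(header + "\n")
        np.savetxt(fh, G.values, delimiter=",")


def read_evidence(path) -> EvidenceMatrix:
    with open(path) as fh:
        first = fh.readline().strip()
        kind = first.split("kind=")[1] if "kind=" in first else "combined"
        values = np.loadtxt(fh, delimiter=",")
    return EvidenceMatrix(values, kind=kind)


# --------------------------------------------------------- run manifest

def _fingerprint(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Everything needed to reproduce one CLI run bit for bit."""

    seed: int | None
    config: dict = field(default_factory=dict)
    partition_counts: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)   # path → content fingerprint
    outputs: list = field(default_factory=list)
    version: str = ""

    def add_input(self, path) -> None:
        self.inputs[str(path)] = _fingerprint(path)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str) + "\n")

    @classmethod
    def load(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
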