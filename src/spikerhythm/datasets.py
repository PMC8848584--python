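"""Labeled ISI datasets: mechanistic and archetypal generators plus CSV I/O.

The default experiment uses four rhythm classes — periodic (PD, label 0),
random-alternating cluster (RD, 1), chaotic (CD, 2) and integer-multiple
(IMD, 3) — with 60 sequences of 1024 intervals per class, split 40 train /
20 test.  Two generator modes exist:

* ``chay`` — run the Chay-model variants configured per class (see
  ``configs/chay_regimes.json``), detect spikes, extract and preprocess ISIs.
  Faithful but expensive (each sequence needs more than a thousand spikes).
* ``archetype`` — statistical surrogates with the same phenomenology:
  near-constant ISIs with slow drift (PD), stochastic alternation between two
  periodic burst motifs (RD), a logistic-map-driven chaotic sequence (CD),
  and integer multiples of a base period (IMD).  Cheap, reproducible, and
  the default for dataset-scale experiments.

Datasets are stored as CSV, one row per sequence: 1024 numeric columns then
an integer ``label`` column.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd

from . import chay as _chay
from .spikes import (CLASS_NAMES, ISISequence, TARGET_LENGTH, detect_spikes,
                     extract_isi, preprocess)

__all__ = [
    "LabeledDataset",
    "build_dataset",
    "generate_archetype",
    "generate_chay_sequence",
    "read_dataset",
    "write_dataset",
    "read_isi_csv",
    "write_isi_csv",
    "load_chay_regimes",
]

N_TRAIN_PER_CLASS = 40
N_TEST_PER_CLASS = 20


@dataclass
class LabeledDataset:
    """Train/test split of labeled, preprocessed ISI sequences."""

    train: List[ISISequence]
    test: List[ISISequence]
    class_names: tuple = CLASS_NAMES
    provenance: dict = field(default_factory=dict)

    def _to_arrays(self, seqs: List[ISISequence]):
        X = np.vstack([s.values for s in seqs])
        y = np.array([s.label for s in seqs], dtype=int)
        return X, y

    @property
    def train_arrays(self):
        return self._to_arrays(self.train)

    @property
    def test_arrays(self):
        return self._to_arrays(self.test)

    def summary(self) -> str:
        Xtr, ytr = self.train_arrays
        Xte, yte = self.test_arrays
        lines = [f"LabeledDataset: {len(self.train)} train / {len(self.test)} test, "
                 f"length {Xtr.shape[1]}"]
        for lbl, name in enumerate(self.class_names):
            lines.append(f"  {name} (label {lbl}): {np.sum(ytr == lbl)} train, "
                         f"{np.sum(yte == lbl)} test")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# archetype surrogates
# ---------------------------------------------------------------------------

# Defaults for the surrogate generators: one base period (arbitrary units,
# removed by per-sequence normalization anyway), jitter levels in the
# few-percent range typical of regular firing, a mildly chaotic logistic map
# and a geometric multiple distribution for spike skipping.
ARCHETYPE_DEFAULTS = {
    "base_period": 1.0,
    "pd_jitter": 0.01,       # total CV of the periodic rhythm
    "pd_mod_period": 128,    # ISIs per cycle of the slow rate modulation
    "pd_white_frac": 0.02,   # fraction of the jitter that is white
    "rd_intra": 0.3,         # intra-burst ISI
    "rd_inter": (2.0, 1.2),  # inter-burst gap of the two cluster motifs
    "rd_counts": (3, 7),     # spikes-per-cluster of the two motifs
    "rd_switch_p": 0.5,      # probability of choosing the first motif
    "rd_jitter": 0.02,
    "cd_r": 3.9,             # logistic-map parameter (chaotic regime)
    "cd_lo": 0.3,            # affine rescaling of the map output
    "cd_span": 1.4,
    "imd_p": 0.55,           # geometric parameter of the multiple k >= 1
    "imd_max_k": 6,
    "imd_jitter": 0.02,
}


def generate_archetype(class_id: int, n_seqs: int, length: int = TARGET_LENGTH,
                       seed=None, params: Optional[dict] = None,
                       rng: Optional[np.random.Generator] = None) -> List[np.ndarray]:
    """Raw (un-normalized) ISI sequences for one rhythm class.

    PD: base period with a slow sinusoidal rate modulation plus a trace of
    white jitter (overall CV ≈ 0.01).  RD: random alternation between two
    periodic cluster motifs.  CD: logistic map iterates rescaled to a
    positive range.  IMD: base period times an integer multiple with
    geometric-like weights.
    """
    if class_id not in (0, 1, 2, 3):
        raise ValueError(f"unknown class_id {class_id}; expected 0..3")
    p = dict(ARCHETYPE_DEFAULTS)
    if params:
        p.update(params)
    if rng is None:
        rng = np.random.default_rng(seed)
    T0 = p["base_period"]
    out = []
    for _ in range(n_seqs):
        if class_id == 0:  # PD
            jit = p["pd_jitter"]
            if jit > 0:
                wf = p["pd_white_frac"]
                period = p["pd_mod_period"] * rng.uniform(0.8, 1.25)
                amp = jit * np.sqrt(2.0) * np.sqrt(1.0 - wf**2)
                i = np.arange(length)
                drift = amp * np.sin(2.0 * np.pi * i / period + rng.uniform(0, 2 * np.pi))
                white = rng.normal(0.0, jit * wf, length)
                x = T0 * (1.0 + drift + white)
            else:
                x = np.full(length, T0)
        elif class_id == 1:  # RD
            isis: list[float] = []
            while len(isis) < length:
                motif = 0 if rng.random() < p["rd_switch_p"] else 1
                count = p["rd_counts"][motif]
                intra = p["rd_intra"] * (1.0 + rng.normal(0.0, p["rd_jitter"], count))
                inter = p["rd_inter"][motif] * (1.0 + rng.normal(0.0, p["rd_jitter"]))
                isis.extend(intra.tolist())
                isis.append(float(inter))
            x = np.array(isis[:length])
        elif class_id == 2:  # CD
            r = p["cd_r"]
            z = rng.uniform(0.1, 0.9)
            for _ in range(100):  # burn-in of the map
                z = r * z * (1.0 - z)
            xs = np.empty(length)
            for i in range(length):
                z = r * z * (1.0 - z)
                xs[i] = z
            x = T0 * (p["cd_lo"] + p["cd_span"] * xs)
        else:  # IMD
            ks = np.arange(1, p["imd_max_k"] + 1)
            w = (1.0 - p["imd_p"]) ** (ks - 1) * p["imd_p"]
            w /= w.sum()
            mult = rng.choice(ks, size=length, p=w)
            jit = rng.normal(0.0, p["imd_jitter"], length) if p["imd_jitter"] > 0 else 0.0
            x = T0 * mult * (1.0 + jit)
        x = np.maximum(x, 1e-6)
        out.append(x)
    return out


# ---------------------------------------------------------------------------
# mechanistic (Chay) generation
# ---------------------------------------------------------------------------

def load_chay_regimes() -> dict:
    """Per-class Chay regime configuration shipped with the package."""
    with resources.files("spikerhythm").joinpath("configs/chay_regimes.json").open() as fh:
        return json.load(fh)


def generate_chay_sequence(regime: dict, length: int = TARGET_LENGTH, seed=None,
                           rng: Optional[np.random.Generator] = None,
                           max_chunks: int = 60) -> np.ndarray:
    """Simulate one Chay run until ``length`` + transient ISIs are available.

    ``regime`` holds the model variant, parameters, noise spec, integration
    step and spike-detection settings (see ``configs/chay_regimes.json``).
    Simulation proceeds in chunks, carrying the state forward, until enough
    spikes accumulate; raises if the budget of ``max_chunks`` is exhausted.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    params = _chay.ChayParams(**regime.get("params", {}))
    dt = regime.get("dt", 0.001)
    threshold = regime.get("threshold", -30.0)
    refractory = regime.get("refractory", 0.05)
    chunk_T = regime.get("chunk_T", 500.0)
    transient = regime.get("transient_isis", 5)
    noise_cfg = regime.get("noise")
    init = _chay.ChayState(V=rng.uniform(-50.0, -25.0), n=rng.uniform(0.1, 0.6),
                           C=rng.uniform(0.3, 1.0))
    spike_times: list[float] = []
    t_offset = 0.0
    needed = length + transient + 1
    for _ in range(max_chunks):
        if noise_cfg:
            spec = _chay.NoiseSpec(**noise_cfg)
            trace = _chay.simulate_stochastic(params, init, spec, dt=dt, T=chunk_T,
                                              rng=rng)
        else:
            trace = _chay.simulate_stochastic(params, init, _chay.NoiseSpec(kind="none"),
                                              dt=dt, T=chunk_T, rng=rng)
        train = detect_spikes(trace, threshold=threshold, refractory=refractory)
        # drop a possible partial spike at the chunk boundary
        times = train.times + t_offset
        if spike_times and len(times) and times[0] - spike_times[-1] < refractory:
            times = times[1:]
        spike_times.extend(times.tolist())
        if len(spike_times) >= needed:
            isi = np.diff(np.array(spike_times))[transient:transient + length]
            return isi
        init = _chay.ChayState(V=float(trace.V[-1]), n=float(trace.n[-1]),
                               C=float(trace.C[-1]))
        t_offset += chunk_T
    raise RuntimeError(
        f"regime produced only {len(spike_times)} spikes within the simulation "
        f"budget ({max_chunks} chunks of T={chunk_T}); need {needed}"
    )


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def build_dataset(config: Optional[dict] = None, seed: int = 0,
                  mode: str = "archetype") -> LabeledDataset:
    """Assemble the paper-shaped labeled dataset.

    Default: 4 classes × (40 train + 20 test) sequences of 1024 normalized
    intervals.  ``mode='chay'`` runs the mechanistic simulators configured in
    ``configs/chay_regimes.json``; ``mode='archetype'`` uses the statistical
    surrogates.  Deterministic for a fixed seed.
    """
    config = dict(config or {})
    n_train = config.get("n_train_per_class", N_TRAIN_PER_CLASS)
    n_test = config.get("n_test_per_class", N_TEST_PER_CLASS)
    length = config.get("length", TARGET_LENGTH)
    normalization = config.get("normalization", "minmax")
    if mode not in ("archetype", "chay"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    regimes = load_chay_regimes() if mode == "chay" else None
    train, test = [], []
    for label, name in enumerate(CLASS_NAMES):
        raws: list[np.ndarray] = []
        if mode == "archetype":
            raws = generate_archetype(label, n_train + n_test, length=length,
                                      params=config.get("archetype_params"), rng=rng)
        else:
            regime = regimes["classes"][name]
            for _ in range(n_train + n_test):
                try:
                    raws.append(generate_chay_sequence(regime, length=length, rng=rng))
                except RuntimeError as exc:
                    raise RuntimeError(f"class {name}: {exc}") from exc
        for i, raw in enumerate(raws):
            seq = preprocess(ISISequence(values=raw, label=label),
                             target_len=length, normalization=normalization)
            (train if i < n_train else test).append(seq)
    prov = {"mode": mode, "seed": seed, "n_train_per_class": n_train,
            "n_test_per_class": n_test, "length": length,
            "normalization": normalization}
    if mode == "archetype":
        prov["archetype_params"] = {**ARCHETYPE_DEFAULTS,
                                    **(config.get("archetype_params") or {})}
    return LabeledDataset(train=train, test=test, provenance=prov)


# ---------------------------------------------------------------------------
# CSV I/O (1024 value columns + a trailing integer `label` column)
# ---------------------------------------------------------------------------

def write_isi_csv(seqs: List[ISISequence], path, header: bool = True) -> None:
    X = np.vstack([s.values for s in seqs])
    y = np.array([s.label for s in seqs], dtype=int)
    df = pd.DataFrame(X, columns=[f"isi_{i:04d}" for i in range(X.shape[1])])
    df["label"] = y
    df.to_csv(path, index=False, header=header)


def read_isi_csv(path, expected_length: int = TARGET_LENGTH) -> List[ISISequence]:
    """Read one dataset file; tolerates header or headerless dialects."""
    with open(path) as fh:
        first = fh.readline()
    tokens = first.strip().split(",")

    def _numeric(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    has_header = not all(_numeric(t) for t in tokens if t != "")
    df = pd.read_csv(path, header=0 if has_header else None)
    if df.shape[1] != expected_length + 1:
        raise ValueError(
            f"{path}: expected {expected_length} value columns plus a label "
            f"column, found {df.shape[1]} columns"
        )
    values = df.iloc[:, :-1].to_numpy(dtype=float)
    labels = df.iloc[:, -1].to_numpy()
    seqs = []
    for i in range(len(df)):
        lab = labels[i]
        if not float(lab).is_integer() or int(lab) not in (0, 1, 2, 3):
            raise ValueError(f"{path}: row {i}: label {lab!r} outside {{0,1,2,3}}")
        row = values[i]
        if not np.all(np.isfinite(row)):
            raise ValueError(f"{path}: row {i}: non-finite values")
        normalized = bool(row.min() >= 0.0 and row.max() <= 1.0)
        seqs.append(ISISequence(values=row, label=int(lab), normalized=normalized))
    return seqs


def write_dataset(ds: LabeledDataset, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_isi_csv(ds.train, out / "train.csv")
    write_isi_csv(ds.test, out / "test.csv")
    with open(out / "provenance.json", "w") as fh:
        json.dump(ds.provenance, fh, indent=2, default=str)


def read_dataset(path) -> LabeledDataset:
    """Read a dataset directory (train.csv/test.csv) or a single CSV file
    (treated as an un-split pool placed in ``train``)."""
    p = Path(path)
    if p.is_dir():
        prov_file = p / "provenance.json"
        prov = json.loads(prov_file.read_text()) if prov_file.exists() else {}
        length = int(prov.get("length", TARGET_LENGTH))
        train = read_isi_csv(p / "train.csv", expected_length=length)
        test = read_isi_csv(p / "test.csv", expected_length=length)
        return LabeledDataset(train=train, test=test, provenance=prov)
    seqs = read_isi_csv(p)
    return LabeledDataset(train=seqs, test=[], provenance={"source": str(p)})
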