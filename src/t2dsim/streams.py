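"""Counter-based random substreams.

The simulation needs random numbers with structural guarantees that a single
sequential generator cannot give:

* per-patient independence — permuting or extending the cohort must not
  perturb any other patient's draws;
* addressability — the draw for (patient, year, purpose) is a pure function
  of the master seed and those labels, so arms sharing a seed share patient
  level randomness (common random numbers) and results are independent of
  execution order.

Both are provided by a keyed counter construction: a 64-bit key per patient
is derived from the master seed, and each uniform is obtained by mixing the
key with integer counters through the SplitMix64 finaliser, whose output is
statistically indistinguishable from uniform for this purpose.  All
operations are vectorised over patients.
"""

from __future__ import annotations

import numpy as np

_GOLDEN = np.uint64(0x9E3779B97F4A7C15)
_MIX1 = np.uint64(0xBF58476D1CE4E5B9)
_MIX2 = np.uint64(0x94D049BB133111EB)
# distinct odd multipliers decorrelate the counter dimensions
_C1 = np.uint64(0xD6E8FEB86659FD93)
_C2 = np.uint64(0xA3B195354A39B70D)


def _mix(x: np.ndarray) -> np.ndarray:
    """SplitMix64 finaliser, elementwise on uint64."""
    with np.errstate(over="ignore"):
        x = np.asarray(x, dtype=np.uint64)
        x = (x ^ (x >> np.uint64(30))) * _MIX1
        x = (x ^ (x >> np.uint64(27))) * _MIX2
        return x ^ (x >> np.uint64(31))


def derive_key(master_seed: int, *labels) -> np.uint64:
    """Derive a 64-bit stream key from a master seed and a label path.

    Labels may be ints or short strings (e.g. ``derive_key(seed, "cohort")``).
    """
    with np.errstate(over="ignore"):
        h = _mix(np.uint64(master_seed & 0xFFFFFFFFFFFFFFFF) * _GOLDEN)
        for lab in labels:
            if isinstance(lab, str):
                for ch in lab.encode():
                    h = _mix(h ^ (np.uint64(ch) * _C1))
            else:
                h = _mix(h ^ (np.uint64(int(lab) & 0xFFFFFFFFFFFFFFFF) * _C1))
        return np.uint64(h)


def patient_keys(master_seed: int, label, n: int) -> np.ndarray:
    """Per-patient keys for patient ids 0..n-1.

    Extending the cohort appends keys without changing existing ones.
    """
    base = derive_key(master_seed, label)
    ids = np.arange(n, dtype=np.uint64)
    with np.errstate(over="ignore"):
        return _mix(base ^ (ids * _C1))


def keys_for_ids(master_seed: int, label, ids: np.ndarray) -> np.ndarray:
    """Keys addressed by stable patient ids (not positions)."""
    base = derive_key(master_seed, label)
    ids = np.asarray(ids, dtype=np.uint64)
    with np.errstate(over="ignore"):
        return _mix(base ^ (ids * _C1))


def uniforms(keys: np.ndarray, *counters: int) -> np.ndarray:
    """One uniform in [0, 1) per key, addressed by integer counters."""
    h = np.asarray(keys, dtype=np.uint64)
    with np.errstate(over="ignore"):
        for i, c in enumerate(counters):
            mult = _C1 if i % 2 == 0 else _C2
            h = _mix(h ^ (np.uint64(int(c)) * mult))
        h = _mix(h)
    return (h >> np.uint64(11)).astype(np.float64) * (2.0 ** -53)


def uniform_block(keys: np.ndarray, counter: int, m: int) -> np.ndarray:
    """(n, m) block of uniforms: slot j is ``uniforms(keys, counter, j)``."""
    out = np.empty((len(keys), m), dtype=np.float64)
    for j in range(m):
        out[:, j] = uniforms(keys, counter, j)
    return out


def random_permutations(keys: np.ndarray, counter: int, m: int) -> np.ndarray:
    """(n, m) array of independent uniform permutations of range(m)."""
    u = uniform_block(keys, counter, m)
    return np.argsort(u, axis=1, kind="stable")
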