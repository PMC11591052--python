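import numpy as np
import pandas as pd
import pytest

from ecdymet.de import CountMatrix


def make_count_matrix(counts, n_control=None):
    """Build a CountMatrix from a 2-D array whose first half of columns is
    the control group (override with n_control)."""
    counts = np.asarray(counts)
    n_samples = counts.shape[1]
    n_control = n_samples // 2 if n_control is None else n_control
    samples = [f"c{i}" for i in range(n_control)] + [
        f"t{i}" for i in range(n_samples - n_control)
    ]
    groups = pd.Series(
        ["control"] * n_control + ["treated"] * (n_samples - n_control), index=samples
    )
    genes = pd.Index([f"g{i}" for i in range(counts.shape[0])], name="gene_id")
    return CountMatrix(counts=pd.DataFrame(counts, index=genes, columns=samples), groups=groups)


@pytest.fixture
def tiny_trace_table():
    """One well, three phases, three measurements each, hand-set values."""
    rows = []
    t = 0.0
    specs = [
        ("basal", [95.0, 98.0, 100.0], [30.0, 31.0, 32.0]),
        ("post_oligomycin", [45.0, 40.0, 42.0], [40.0, 41.0, 42.0]),
        ("post_rotaa", [12.0, 10.0, 11.0], [38.0, 37.0, 36.0]),
    ]
    for phase, ocrs, ecars in specs:
        for ocr, ecar in zip(ocrs, ecars):
            t += 6.5
            rows.append(
                {
                    "well": "A1",
                    "group": "control",
                    "phase": phase,
                    "time_min": t,
                    "ocr_pmol_per_min": ocr,
                    "ecar_mpH_per_min": ecar,
                }
            )
    return pd.DataFrame(rows)
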