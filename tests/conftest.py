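import numpy as np
import pandas as pd
import pytest


def make_peptides(entries):
    """Build a peptide table from (protein, experiment, timepoint, [log2 ratios])."""
    rows = []
    for protein, experiment, tp, log2s in entries:
        for i, v in enumerate(log2s):
            rows.append({"protein_id": protein, "experiment_id": experiment,
                         "timepoint_h": float(tp), "ratio_hm": 2.0 ** v,
                         "peptide_id": f"{protein}_{experiment}_{tp}_{i}"})
    return pd.DataFrame(rows)


def make_estimates(entries):
    """Build an estimate table from (protein, experiment, timepoint, log2, n_peptides)."""
    return pd.DataFrame(
        [{"protein_id": p, "experiment_id": e, "timepoint_h": float(t),
          "log2_ratio": float(v), "n_peptides": int(n)} for p, e, t, v, n in entries])


@pytest.fixture
def filter_fixture_peptides():
    """Four proteins with (total peptides, experiments) = (5,3), (4,3), (7,2), (10,5)."""
    entries = []
    for pid, counts in (("A", [2, 2, 1]), ("B", [2, 1, 1]),
                        ("C", [4, 3]), ("D", [2, 2, 2, 2, 2])):
        for j, n in enumerate(counts):
            entries.append((pid, f"E{j + 1}", 8.0, [-0.1] * n))
    return make_peptides(entries)


@pytest.fixture
def spot_field():
    """256x256 noisy field with 50 planted Gaussian spots at SNR 5."""
    rng = np.random.default_rng(7)
    noise_sd, amplitude, sigma_spot = 10.0, 50.0, 2.0
    img = rng.normal(100.0, noise_sd, (256, 256))
    centers = []
    while len(centers) < 50:
        c = rng.integers(15, 241, 2)
        if all((c[0] - a) ** 2 + (c[1] - b) ** 2 > 14 ** 2 for a, b in centers):
            centers.append((int(c[0]), int(c[1])))
    yy, xx = np.mgrid[0:256, 0:256]
    for a, b in centers:
        img += amplitude * np.exp(-((yy - a) ** 2 + (xx - b) ** 2) / (2 * sigma_spot ** 2))
    return img, np.array(centers)
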