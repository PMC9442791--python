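import numpy as np
import pandas as pd
import pytest

from tmtkit.matrix import AbundanceMatrix
from tmtkit.simulate import QUANT_META_COLUMNS


def make_quant_table(rows, sample_cols, plex_id="plex1"):
    """Build a QuantTable DataFrame from dicts of meta + per-channel values."""
    records = []
    for r in rows:
        rec = {
            "peptide_id": r.get("peptide_id", f"pep{len(records)}"),
            "peptide_sequence": r.get("peptide_sequence", "PEPTIDEK"),
            "species": r.get("species", "human"),
            "master_proteins": r.get("master_proteins", "P1"),
            "id_score": r.get("id_score", 300.0),
            "plex_id": r.get("plex_id", plex_id),
            "phospho_positions": r.get("phospho_positions", ""),
            "localization_ambiguous": r.get("localization_ambiguous", False),
        }
        for c in sample_cols:
            rec[c] = r.get(c, np.nan)
        records.append(rec)
    return pd.DataFrame(records, columns=QUANT_META_COLUMNS + list(sample_cols))


def make_matrix(values, plex_ids=None, reference=None):
    """AbundanceMatrix from a features x samples DataFrame."""
    values = pd.DataFrame(values)
    cols = list(values.columns)
    plex_ids = plex_ids or {c: "plex1" for c in cols}
    reference = reference or set()
    samples = pd.DataFrame(
        {
            "plex_id": [plex_ids[c] for c in cols],
            "channel_id": [f"ch{i + 1:02d}" for i in range(len(cols))],
            "is_reference": [c in reference for c in cols],
        },
        index=pd.Index(cols, name="sample_id"),
    )
    return AbundanceMatrix(values, samples)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_experiment():
    """A seeded two-plex experiment with batch effects, noise and planted DE."""
    from tmtkit.simulate import SimConfig, generate_experiment

    cfg = SimConfig(
        seed=11,
        n_proteins=200,
        n_samples=20,
        plex_effect_sd=0.4,
        noise_sd=0.25,
        missing_rate=0.03,
        frac_mouse=0.1,
        frac_shared=0.05,
        group_effect_size=1.5,
        drug_effect=0.8,
    )
    tables, truth = generate_experiment(cfg)
    return cfg, tables, truth
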