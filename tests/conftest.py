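import numpy as np
import pandas as pd
import pytest

import trflpkit as tk


@pytest.fixture(scope="session")
def base_community():
    """The bundled 5-phylotype ground-truth community (known abundances)."""
    return tk.fixture_community()


@pytest.fixture(scope="session")
def noiseless_chain(base_community):
    """Noiseless single-run profile processed through the full chain."""
    prof = tk.simulate_profiles(base_community, tk.NoiseModel.noiseless(),
                                n_replicates=1, seed=3)[0]
    binned = tk.abundance_filter(tk.bin_peaks(tk.filter_peaks(prof)))
    return prof, binned


def make_profile(peaks, sample_id="s1"):
    """PeakProfile from (size, height, area, dye) tuples."""
    return tk.PeakProfile(sample_id, [tk.Peak(*p) for p in peaks])


def make_binned(rows, sample_id="s1"):
    """BinnedProfile from (dye, size, area) tuples; abundances normalized."""
    bins = pd.DataFrame(rows, columns=["dye", "size_bp", "area"])
    bins["rel_abundance"] = bins["area"] / bins["area"].sum()
    return tk.BinnedProfile(sample_id, bins)
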