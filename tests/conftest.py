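import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from irgloss import IRG_CLASSES, IRGClass, PanGeneMatrix, RepertoireCounts

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


def make_counts(species_id: str, **kwargs) -> RepertoireCounts:
    """RepertoireCounts from keyword class counts, rest zero."""
    counts = {IRGClass(k): v for k, v in kwargs.items()}
    return RepertoireCounts(species_id=species_id, counts=counts)


def make_pangene(rows, triplicate_id="trip", crop="crop_sp", wild="wild_sp",
                 outgroup="out_sp") -> PanGeneMatrix:
    """PanGeneMatrix from (crop, wild, outgroup, has_ref, is_irg) tuples."""
    table = pd.DataFrame(
        [
            {
                "orthogroup_id": f"og{i}",
                "crop": bool(c),
                "wild": bool(w),
                "outgroup": bool(o),
                "outgroup_gene_id": f"g{i}" if ref else "",
                "is_irg": bool(irg),
            }
            for i, (c, w, o, ref, irg) in enumerate(rows)
        ]
    )
    return PanGeneMatrix(
        triplicate_id=triplicate_id, crop_species=crop, wild_species=wild,
        outgroup_species=outgroup, table=table,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
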