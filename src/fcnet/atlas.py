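"""Region definitions for the 90-region automated anatomical labelling (AAL) parcellation.

The cerebrum is divided into 90 cortical/subcortical regions (45 homologous
pairs; odd atlas indices are left-hemisphere, even are right). Each region is
one node of the functional network; node order throughout the package follows
the atlas index order, so node ``i`` (0-based) is atlas region ``i + 1``.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

N_REGIONS = 90

#: 0-based node index of the right amygdala (atlas region 42), the default
#: site of the planted nodal deficit in the synthetic cohort.
RIGHT_AMYGDALA = 41


def load_regions() -> pd.DataFrame:
    """Return the 90-row region table (index, label, abbreviation, hemisphere, name).

    ``index`` is the 1-based atlas index; ``label`` is the abbreviation with a
    hemisphere suffix (e.g. ``AMYG.R``) and is unique.
    """
    with resources.files("fcnet.data").joinpath("aal90_regions.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    if len(df) != N_REGIONS:
        raise RuntimeError(f"atlas table has {len(df)} rows, expected {N_REGIONS}")
    return df


def region_labels() -> list[str]:
    """The 90 unique region labels in node order (``PreCG.L``, ``PreCG.R``, ...)."""
    return list(load_regions()["label"])
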