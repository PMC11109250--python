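"""Small shared builders for hand-written fixtures."""

import numpy as np
import scipy.sparse as sp

from homomap import ExpressionDataset


def dataset_from_dense(dense, types, species_tag="x", region=None):
    dense = np.asarray(dense, dtype=int)
    return ExpressionDataset(
        species_tag=species_tag,
        gene_ids=[f"g{i}" for i in range(dense.shape[0])],
        cell_ids=[f"{species_tag}c{i}" for i in range(dense.shape[1])],
        counts=sp.csr_matrix(dense),
        cell_type=np.array(types, dtype=object),
        region=None if region is None else np.array(region, dtype=object),
    )
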