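"""Shared helper: wrap a raw weight matrix in a no-op-scaled model."""

import numpy as np

from aclspeech.acl_core import ACLModel


def make_identity_model(W):
    W = np.asarray(W, dtype=float)
    D, K = W.shape
    return ACLModel(
        W=W,
        target_names=tuple(f"T{k}" for k in range(K)),
        target_groups=tuple("G" for _ in range(K)),
        feature_names=tuple(f"F{i}" for i in range(D)),
        feature_center=np.zeros(D),
        feature_scale=np.ones(D),
        target_center=np.zeros(K),
        target_scale=np.ones(K),
        lambda1=0.1,
        lambda2=0.1,
    )
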