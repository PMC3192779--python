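"""Packaged receptor-signature fixtures and the probe IDs used in practice.

The three shipped signature files carry the published per-probe-set Spearman
coefficients and selection cutoffs (24-gene ER at 0.43, 14-gene ERBB2 at
0.35, 51-gene PR at 0.38). The per-row Affymetrix probe-set IDs are not part
of the printed tables, so the files use gene-symbol-derived placeholder IDs
(synthetic, as the filenames state); the single probe IDs that are public —
205225_at (ESR1), 203497_at (PPARBP), 219197_s_at (SCUBE2) — appear
verbatim. The fixtures exercise the signature-file predict path; re-deriving
real signatures requires the original HG-U133A datasets.
"""

from importlib import resources

from ..data import Signature
from ..io import read_signature

__all__ = [
    "load_published_signature",
    "PUBLISHED_SINGLE_PROBES",
    "BEST_PROBES",
]

_FILES = {
    "ER": "er_24gene_synthetic_probes.tsv",
    "ERBB2": "erbb2_14gene_synthetic_probes.tsv",
    "PR": "pr_51gene_synthetic_probes.tsv",
}

#: single probe sets conventionally used in the literature for each receptor
PUBLISHED_SINGLE_PROBES = {"ER": "205225_at", "ERBB2": "216836_s_at", "PR": "208305_at"}

#: highest-signed-rho probe within each published signature
BEST_PROBES = {"ER": "205225_at", "ERBB2": "203497_at", "PR": "219197_s_at"}


def load_published_signature(receptor: str) -> Signature:
    """Load the packaged signature fixture for ``receptor``."""
    if receptor not in _FILES:
        raise KeyError(f"no packaged signature for receptor {receptor!r}")
    ref = resources.files(__package__) / _FILES[receptor]
    with resources.as_file(ref) as path:
        return read_signature(path)
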