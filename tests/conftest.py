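import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests/_oracle.py

from protrp.synth import default_family_specs, make_dataset  # noqa: E402
from protrp.trdetect import detect_repeats  # noqa: E402
from protrp.filters import is_clusterable, is_pro_rich  # noqa: E402


@pytest.fixture(scope="session")
def family_dataset():
    """Five planted motif families x 30 members, 5% substitution — the
    standard recovery conditions; shared across tests."""
    specs = default_family_specs(seed=1)
    records, annotations, truth = make_dataset(specs, decoys=0, seed=1)
    return records, annotations, truth


@pytest.fixture(scope="session")
def family_domains(family_dataset):
    """Best clusterable Pro-rich TR domain per planted protein plus its
    planted family label."""
    records, _, truth = family_dataset
    fam = dict(zip(truth["id"], truth["family"]))
    domains, labels = [], []
    for rec in records:
        doms = [d for d in detect_repeats(rec)
                if is_clusterable(d) and is_pro_rich(d)]
        if not doms:
            continue
        best = max(doms, key=lambda d: d.length)
        domains.append(best)
        labels.append(fam[rec.id])
    return domains, labels
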