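"""Shared fixtures: one synthetic benchmark corpus per session, plus the
expensive derived artifacts (null model, planted-query searches, noise
sweep) reused across test modules."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pytest

from ddiscape import (
    align_interfaces,
    apply_domain_definitions,
    build_interface,
    calibrate_significance,
    make_benchmark_suite,
    parse_structure,
    read_domain_table,
)

SUITE_SEED = 1234


@pytest.fixture(scope="session")
def suite_dir(tmp_path_factory) -> Path:
    out = tmp_path_factory.mktemp("corpus")
    make_benchmark_suite(out, seed=SUITE_SEED)
    return out


@pytest.fixture(scope="session")
def corpus(suite_dir):
    """Corpus re-parsed from disk: chains, two-domain interfaces, truth."""
    defs = read_domain_table(suite_dir / "domains.tsv")
    by_entry = {}
    for d in defs:
        by_entry.setdefault(d.entry_id, []).append(d)
    truth = json.loads((suite_dir / "truth.json").read_text())
    chains, interfaces = {}, {}
    for pdb in sorted(suite_dir.glob("*.pdb")):
        eid = pdb.stem
        chain = parse_structure(pdb.read_text(), "A")
        chain.entry_id = eid
        chain.resolution = by_entry[eid][0].resolution
        chain = apply_domain_definitions(chain, by_entry[eid])
        chains[eid] = chain
        if len(chain.domains) == 2:
            iface = build_interface(*chain.domains)
            iface.pair_id = eid
            interfaces[eid] = iface
    return {"dir": suite_dir, "chains": chains, "interfaces": interfaces,
            "truth": truth["entries"]}


@pytest.fixture(scope="session")
def decoy_ids(corpus):
    return sorted(e for e in corpus["interfaces"] if e.startswith("DEC"))


@pytest.fixture(scope="session")
def planted_ids(corpus):
    return sorted(e for e in corpus["interfaces"] if e.startswith("PLT"))


@pytest.fixture(scope="session")
def null_scores(corpus, decoy_ids):
    """IS-scores of random (decoy-vs-decoy) interface pairs: the null."""
    ids = decoy_ids[:15]
    scores = []
    for q in ids:
        for t in ids:
            if q != t:
                _, sc = align_interfaces(corpus["interfaces"][q],
                                         corpus["interfaces"][t])
                scores.append(sc.IS_score)
    return np.array(scores)


@pytest.fixture(scope="session")
def significance(null_scores):
    return calibrate_significance(null_scores)


@pytest.fixture(scope="session")
def planted_search(corpus, decoy_ids, planted_ids):
    """For each planted query: IS-score against every decoy template and
    against the source interface it was planted from."""
    src = corpus["interfaces"]["SRC1_A"]
    out = {}
    for pid in planted_ids:
        query = corpus["interfaces"][pid]
        scores = {}
        for did in decoy_ids:
            _, sc = align_interfaces(query, corpus["interfaces"][did])
            scores[did] = sc.IS_score
        _, sc = align_interfaces(query, src)
        scores["SRC1_A"] = sc.IS_score
        out[pid] = {
            "scores": scores,
            "sigma": corpus["truth"][pid]["truth"]["noise_sigma"],
        }
    return out
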