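"""Shared fixtures: one default paired simulation reused across the suite."""

from __future__ import annotations

import numpy as np
import pytest

import hicarch as h
from hicarch.simulate import decay_only_config


@pytest.fixture(scope="session")
def sim1():
    """Default two-condition simulation (seed 1) with balanced matrices."""
    cfg = h.default_config(seed=1)
    m1, m2, genes, degs, truth = h.simulate_pair(cfg)
    b1, b2 = h.balance(m1), h.balance(m2)
    e1, e2 = h.expected_profile(b1), h.expected_profile(b2)
    return {
        "cfg": cfg, "m1": m1, "m2": m2, "genes": genes, "degs": degs,
        "truth": truth, "b1": b1, "b2": b2, "e1": e1, "e2": e2,
        "oe1": h.oe_transform(b1, e1), "oe2": h.oe_transform(b2, e2),
    }


@pytest.fixture(scope="session")
def decay_sim():
    """Pure distance-decay simulation (no compartments/domains/loops)."""
    cfg = decay_only_config(seed=1)
    m1, _, genes, _, truth = h.simulate_pair(cfg)
    b1 = h.balance(m1)
    return {"cfg": cfg, "m1": m1, "genes": genes, "truth": truth,
            "b1": b1, "e1": h.expected_profile(b1)}


@pytest.fixture(scope="session")
def class_map(sim1):
    """Pipeline-derived architecture classes for the default simulation."""
    t1 = h.call_compartments(sim1["oe1"], sim1["genes"])
    t2 = h.call_compartments(sim1["oe2"], sim1["genes"])
    cc = h.compare_compartments(t1, t2)
    d1 = h.call_domains(sim1["b1"])
    d2 = h.call_domains(sim1["b2"])
    dcmp = h.compare_domains(d1, d2)
    return h.RegionClassMap.from_comparisons(cc, dcmp)


def boundary_metrics(domset, truth, cond=1, tol=1):
    """(recall, spurious fraction, n called) of domain-set boundaries vs truth."""
    hit = tot = spur = called_tot = 0
    for chrom in truth.genome.names:
        true_b = sorted({b for s, e in truth.domains[cond][chrom] for b in (s, e)})
        called = [int(x) for x in domset.boundaries(chrom)]
        called_tot += len(called)
        for t in true_b:
            tot += 1
            if any(abs(t - x) <= tol for x in called):
                hit += 1
        for x in called:
            if not any(abs(t - x) <= tol for t in true_b):
                spur += 1
    return hit / tot, spur / max(called_tot, 1), called_tot


def loop_metrics(called_pixels, truth_pixels, tol=1):
    """(recall, precision) of called loop pixels vs truth pixels."""
    truth_pixels = list(truth_pixels)
    called_pixels = list(called_pixels)
    hit = sum(
        1 for c, i, j in called_pixels
        if any(c == tc and abs(i - ti) <= tol and abs(j - tj) <= tol
               for tc, ti, tj in truth_pixels)
    )
    rec = sum(
        1 for tc, ti, tj in truth_pixels
        if any(c == tc and abs(i - ti) <= tol and abs(j - tj) <= tol
               for c, i, j in called_pixels)
    )
    return rec / max(len(truth_pixels), 1), hit / max(len(called_pixels), 1)


def flip_metrics(comparison, track1, track2, truth):
    """(precision, recall) of changed-compartment bins vs truth flips."""
    tp = fp = fn = 0
    for chrom in truth.genome.names:
        pred = comparison.changed_bins(chrom)
        true = truth.changed_compartment_bins[chrom]
        ok = ~np.isnan(track1.values[chrom]) & ~np.isnan(track2.values[chrom])
        tp += int((pred & true & ok).sum())
        fp += int((pred & ~true & ok).sum())
        fn += int((~pred & true & ok).sum())
    return tp / max(tp + fp, 1), tp / max(tp + fn, 1)
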