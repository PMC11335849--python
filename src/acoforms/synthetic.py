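"""Synthetic 2PL item banks and grouped response data.

Generates item pools organized as domains x items-per-domain (default
12 x 10, mirroring a broad knowledge test with ten items per domain) with
known generating parameters, optional focal-group DIF on a named item
subset, and binary response matrices for a reference and a focal group.
Because the generating truth is known, every downstream stage — 2PL
recovery, fit statistics, DTF, threshold calibration, the ACO search — can
be validated without external data.

Response model (reference group):  P(X=1 | theta) = logistic(a (theta - b));
focal group:  P = logistic(a * dif_a * (theta - b - dif_b)).
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from .bank import ItemBank, ItemSpec, ResponseData

__all__ = [
    "generate_item_bank",
    "simulate_responses",
    "plant_dominant_triple",
    "default_bank",
]


def _draw(dist: dict, size: int, rng: np.random.Generator, positive: bool = False) -> np.ndarray:
    """Draw from a small family of distribution specs.

    Specs: {"dist": "lognormal", "mean": m, "sigma": s},
    {"dist": "normal", "mean": m, "sd": s}, {"dist": "uniform", "lo": a,
    "hi": b}, {"dist": "fixed", "value": v}.
    """
    kind = dist.get("dist")
    if kind == "lognormal":
        out = rng.lognormal(dist.get("mean", 0.0), dist.get("sigma", 0.25), size)
    elif kind == "normal":
        out = rng.normal(dist.get("mean", 0.0), dist.get("sd", 1.0), size)
    elif kind == "uniform":
        lo, hi = dist["lo"], dist["hi"]
        if hi <= lo:
            raise ValueError(f"uniform bounds must satisfy lo < hi, got ({lo}, {hi})")
        if positive and lo <= 0:
            raise ValueError(f"discrimination lower bound must be > 0, got {lo}")
        out = rng.uniform(lo, hi, size)
    elif kind == "fixed":
        out = np.full(size, float(dist["value"]))
    else:
        raise ValueError(f"unknown distribution spec {dist!r}")
    if positive and np.any(out <= 0):
        raise ValueError("discrimination draws must be positive; tighten the spec")
    return out


def generate_item_bank(
    n_domains: int = 12,
    items_per_domain: int = 10,
    a_dist: dict | None = None,
    b_dist: dict | None = None,
    dif_config: dict | None = None,
    seed: int = 0,
) -> ItemBank:
    """Generate a domains x items 2PL bank with optional planted DIF.

    ``dif_config`` names the focal-group offsets:
    ``{"items": [item ids], "dif_a": 1.0, "dif_b": 0.5}``.  Item ids follow
    the scheme ``dom01_i01`` (domain then item within domain).  Defaults:
    a ~ logNormal(0, 0.25), b ~ Normal(0, 1), no DIF.
    """
    if n_domains < 1 or items_per_domain < 1:
        raise ValueError("n_domains and items_per_domain must be >= 1")
    a_dist = a_dist if a_dist is not None else {"dist": "lognormal", "mean": 0.0, "sigma": 0.25}
    b_dist = b_dist if b_dist is not None else {"dist": "normal", "mean": 0.0, "sd": 1.0}
    rng = np.random.default_rng(seed)
    n = n_domains * items_per_domain
    a = _draw(a_dist, n, rng, positive=True)
    b = _draw(b_dist, n, rng)

    dif_items: set[str] = set()
    dif_a, dif_b = 1.0, 0.0
    if dif_config:
        dif_items = set(dif_config.get("items", []))
        dif_a = float(dif_config.get("dif_a", 1.0))
        dif_b = float(dif_config.get("dif_b", 0.0))
        if dif_a <= 0:
            raise ValueError("dif_a must keep the focal discrimination positive")

    items = []
    domains = [f"dom{d + 1:02d}" for d in range(n_domains)]
    idx = 0
    for d, dom in enumerate(domains):
        for j in range(items_per_domain):
            iid = f"{dom}_i{j + 1:02d}"
            has_dif = iid in dif_items
            items.append(
                ItemSpec(
                    item_id=iid,
                    domain=dom,
                    a_true=float(a[idx]),
                    b_true=float(b[idx]),
                    dif_a=dif_a if has_dif else 1.0,
                    dif_b=dif_b if has_dif else 0.0,
                )
            )
            idx += 1
    bank = ItemBank(items=items, domains=domains)
    unknown = dif_items - set(bank.item_ids)
    if unknown:
        raise ValueError(f"dif_config names unknown items: {sorted(unknown)}")
    return bank


def default_bank(seed: int = 0) -> ItemBank:
    """The default study pool: 12 domains x 10 items, no DIF."""
    return generate_item_bank(12, 10, seed=seed)


def simulate_responses(
    bank: ItemBank,
    n_per_group=(400, 400),
    theta_dist=((0.0, 1.0), (0.0, 1.0)),
    seed: int = 0,
    group_labels=("ref", "focal"),
) -> ResponseData:
    """Simulate binary responses for a reference and a focal group.

    ``n_per_group`` may be an int (single unlabeled group, reference
    parameters) or a pair; ``theta_dist`` gives per-group (mean, sd) of the
    latent ability.  Focal-group item parameters apply the bank's DIF
    offsets.  Identical seeds yield identical matrices.
    """
    if len(bank) == 0:
        raise ValueError("empty item bank")
    rng = np.random.default_rng(seed)
    frame = bank.params_frame()
    a = frame["a_true"].to_numpy()
    b = frame["b_true"].to_numpy()
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("bank has items without generating parameters")

    single = np.isscalar(n_per_group)
    if single:
        n_per_group = (int(n_per_group),)
        theta_dist = (theta_dist[0] if isinstance(theta_dist[0], (tuple, list)) else theta_dist,)
        group_labels = (group_labels[0],)
    if any(int(n) < 0 for n in n_per_group) or sum(int(n) for n in n_per_group) < 1:
        raise ValueError("group sizes must be nonnegative and sum to >= 1")

    blocks, labels = [], []
    for g, (n_g, (mu, sd), lvl) in enumerate(zip(n_per_group, theta_dist, group_labels)):
        n_g = int(n_g)
        if n_g == 0:
            continue
        theta = rng.normal(mu, sd, n_g)
        if g == 0:
            a_g, b_g = a, b
        else:
            a_g = a * frame["dif_a"].to_numpy()
            b_g = b + frame["dif_b"].to_numpy()
        p = expit(a_g[None, :] * (theta[:, None] - b_g[None, :]))
        blocks.append((rng.random((n_g, len(bank))) < p).astype(np.int8))
        labels.extend([lvl] * n_g)
    responses = np.vstack(blocks)
    if single:
        return ResponseData(responses, bank.item_ids)
    return ResponseData(
        responses, bank.item_ids, group=np.array(labels), group_levels=list(group_labels)
    )


def plant_dominant_triple(
    bank: ItemBank,
    target_sets: list[list[str]],
    planted_a: float = 2.0,
    background_a: float = 0.4,
    background_dif_b: float = 0.8,
) -> ItemBank:
    """Rebuild a bank so a known disjoint triple is near-optimal.

    The three named sets (disjoint, one item per domain each) receive a
    uniformly high discrimination, domain-matched difficulties and zero DIF;
    all remaining items receive low discrimination and a large uniform DIF
    offset.  The planted triple then dominates on reliability, curve
    matching and fairness simultaneously — a recovery fixture for the
    search.
    """
    sets = [list(s) for s in target_sets]
    flat = [iid for s in sets for iid in s]
    if len(set(flat)) != len(flat):
        raise ValueError("target sets overlap")
    for s in sets:
        doms = [bank.by_id(iid).domain for iid in s]  # KeyError on unknown ids
        if sorted(doms) != sorted(bank.domains):
            raise ValueError(
                "each target set must contain exactly one item per domain"
            )
    planted = set(flat)
    # one shared difficulty per domain so planted forms have matching curves
    domain_b = {}
    for dom in bank.domains:
        cand = [bank.by_id(iid).b_true for iid in flat if bank.by_id(iid).domain == dom]
        domain_b[dom] = float(np.clip(np.mean(cand), -1.5, 1.5))
    items = []
    for it in bank.items:
        if it.item_id in planted:
            items.append(
                ItemSpec(it.item_id, it.domain, planted_a, domain_b[it.domain], 1.0, 0.0)
            )
        else:
            items.append(
                ItemSpec(
                    it.item_id,
                    it.domain,
                    background_a,
                    it.b_true,
                    1.0,
                    background_dif_b,
                )
            )
    return ItemBank(items=items, domains=list(bank.domains))
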