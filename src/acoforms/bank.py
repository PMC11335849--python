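"""Item banks and grouped binary response data.

An :class:`ItemBank` describes a calibrated pool of dichotomous items under
the two-parameter logistic (2PL) model: each item has a discrimination
``a_true > 0`` and a difficulty ``b_true`` on the latent-ability (theta)
scale.  Items carry a content-domain label; parallel-form assembly draws one
item per domain into every form.  Optional focal-group DIF offsets
(multiplicative on ``a``, additive on ``b``) let synthetic banks plant known
measurement bias.

A :class:`ResponseData` holds a persons x items 0/1 matrix plus a two-level
group label per person (e.g. women/men) used for differential test
functioning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ItemSpec", "ItemBank", "ResponseData"]


@dataclass(frozen=True)
class ItemSpec:
    """One item of a 2PL bank.

    Parameters
    ----------
    item_id : str
        Unique identifier.
    domain : str
        Content-domain label.
    a_true : float
        Generating discrimination, > 0 (logistic metric, D = 1).
    b_true : float
        Generating difficulty in theta units.
    dif_a : float
        Focal-group multiplicative offset on discrimination (1 = no DIF).
    dif_b : float
        Focal-group additive offset on difficulty (0 = no DIF).
    """

    item_id: str
    domain: str
    a_true: float = np.nan
    b_true: float = np.nan
    dif_a: float = 1.0
    dif_b: float = 0.0

    def __post_init__(self) -> None:
        if np.isfinite(self.a_true) and self.a_true <= 0:
            raise ValueError(f"item {self.item_id!r}: a_true must be > 0")
        if np.isfinite(self.a_true) and self.a_true * self.dif_a <= 0:
            raise ValueError(f"item {self.item_id!r}: focal discrimination must be > 0")


@dataclass
class ItemBank:
    """Ordered collection of :class:`ItemSpec` grouped into content domains."""

    items: list[ItemSpec]
    domains: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise ValueError("item_ids must be unique")
        if not self.domains:
            seen: dict[str, None] = {}
            for it in self.items:
                seen.setdefault(it.domain, None)
            self.domains = list(seen)
        unknown = {it.domain for it in self.items} - set(self.domains)
        if unknown:
            raise ValueError(f"items reference undeclared domains: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.items)

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    def by_id(self, item_id: str) -> ItemSpec:
        try:
            return next(it for it in self.items if it.item_id == item_id)
        except StopIteration:
            raise KeyError(item_id) from None

    def domain_items(self, domain: str) -> list[str]:
        return [it.item_id for it in self.items if it.domain == domain]

    def check_coverage(self, n_forms: int) -> None:
        """Raise unless every domain holds at least ``n_forms`` items."""
        for dom in self.domains:
            n = len(self.domain_items(dom))
            if n < n_forms:
                raise ValueError(
                    f"domain {dom!r} has {n} items; assembling {n_forms} disjoint "
                    f"forms with one item per domain needs at least {n_forms}"
                )

    def params_frame(self) -> pd.DataFrame:
        """Bank as a DataFrame (columns: item_id, domain, a_true, b_true, dif_a, dif_b)."""
        return pd.DataFrame(
            {
                "item_id": [it.item_id for it in self.items],
                "domain": [it.domain for it in self.items],
                "a_true": [it.a_true for it in self.items],
                "b_true": [it.b_true for it in self.items],
                "dif_a": [it.dif_a for it in self.items],
                "dif_b": [it.dif_b for it in self.items],
            }
        )


@dataclass
class ResponseData:
    """Persons x items binary matrix with a per-person two-level group label.

    ``responses`` has shape (n_persons, n_items) with entries in {0, 1};
    ``item_ids`` gives the column order; ``group`` is an array of group labels
    (any hashable scalar), with the first level in ``group_levels`` acting as
    the reference group for DTF.
    """

    responses: np.ndarray
    item_ids: list[str]
    group: np.ndarray | None = None
    group_levels: list | None = None

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses)
        if self.responses.ndim != 2:
            raise ValueError("responses must be a 2-D matrix")
        if self.responses.shape[1] != len(self.item_ids):
            raise ValueError("item_ids must match the number of response columns")
        vals = np.unique(self.responses)
        if not np.isin(vals, [0, 1]).all():
            bad = vals[~np.isin(vals, [0, 1])]
            raise ValueError(f"responses must be binary; found {bad.tolist()}")
        self.responses = self.responses.astype(np.int8)
        if self.group is not None:
            self.group = np.asarray(self.group)
            if len(self.group) != self.responses.shape[0]:
                raise ValueError("group must have one label per person")
            levels = list(pd.unique(self.group))
            if self.group_levels is None:
                self.group_levels = levels
            elif set(levels) - set(self.group_levels):
                raise ValueError("group contains labels outside group_levels")

    @property
    def n_persons(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    def subset(self, item_ids: list[str]) -> "ResponseData":
        """Restrict the columns to ``item_ids`` (in that order)."""
        index = {iid: j for j, iid in enumerate(self.item_ids)}
        missing = [iid for iid in item_ids if iid not in index]
        if missing:
            raise KeyError(f"unknown item ids: {missing}")
        cols = [index[iid] for iid in item_ids]
        return ResponseData(
            self.responses[:, cols],
            list(item_ids),
            group=self.group,
            group_levels=self.group_levels,
        )

    def split_groups(self) -> dict:
        """Response matrices per group level, reference first."""
        if self.group is None:
            raise ValueError("no group labels attached")
        if len(self.group_levels) != 2:
            raise ValueError(
                f"exactly two group levels required, found {self.group_levels}"
            )
        return {
            lvl: self.responses[self.group == lvl] for lvl in self.group_levels
        }
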