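"""Plain-text serialization of webs, communities and TIM sets.

Everything round-trips losslessly: floats are written with shortest
round-trippable ``repr`` (CSV via pandas, scalars via JSON), so a
save -> load -> save cycle is byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import Community
from .params import LinkParams, SpeciesParams
from .tims import TIMSet
from .webgen import FoodWeb

__all__ = [
    "save_web",
    "load_web",
    "save_tims",
    "load_tims",
    "save_community",
    "load_community",
]


def save_web(web: FoodWeb, path: str | Path) -> None:
    """Write a web as ``<path>.csv`` (edge list) + ``<path>.json`` sidecar."""
    path = Path(path)
    pd.DataFrame({
        "consumer": web.consumers, "resource": web.resources,
    }).to_csv(path.with_suffix(".csv"), index=False)
    sidecar = {
        "S": web.S,
        "target_C": web.target_C,
        "seed": web.seed,
        "niche_values": [float(v) for v in web.niche_values],
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_web(path: str | Path) -> FoodWeb:
    path = Path(path)
    edges = pd.read_csv(path.with_suffix(".csv"), float_precision="round_trip")
    meta = json.loads(path.with_suffix(".json").read_text())
    return FoodWeb(
        S=int(meta["S"]),
        consumers=edges.consumer.to_numpy(dtype=np.int64),
        resources=edges.resource.to_numpy(dtype=np.int64),
        niche_values=np.array(meta["niche_values"], dtype=float),
        target_C=float(meta["target_C"]),
        seed=meta["seed"],
    )


def save_tims(tims: TIMSet, path: str | Path) -> None:
    pd.DataFrame({
        "resource": tims.resource, "consumer": tims.consumer,
        "modifier": tims.modifier, "alpha": tims.alpha, "tau": tims.tau,
        "sigma": tims.sigma, "Bk_star": tims.Bk_star,
        "link_index": tims.link_index,
    }).to_csv(path, index=False)


def load_tims(path: str | Path,
              max_per_interaction: int | None = None) -> TIMSet:
    df = pd.read_csv(path, float_precision="round_trip")
    return TIMSet(
        resource=df.resource.to_numpy(np.int64),
        consumer=df.consumer.to_numpy(np.int64),
        modifier=df.modifier.to_numpy(np.int64),
        alpha=df.alpha.to_numpy(float),
        tau=df.tau.to_numpy(float),
        sigma=df.sigma.to_numpy(float),
        Bk_star=df.Bk_star.to_numpy(float),
        link_index=df.link_index.to_numpy(np.int64),
        max_per_interaction=max_per_interaction,
    )


def save_community(community: Community, directory: str | Path) -> None:
    """Write a community bundle (web, species, links, state) to a dir."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    save_web(community.web, d / "web")
    sp = community.species
    pd.DataFrame({
        "M": sp.M, "r": sp.r, "K": sp.K, "m": sp.m, "level": sp.level,
    }).to_csv(d / "species.csv", index=False)
    lk = community.links
    pd.DataFrame({
        "resource": lk.resource, "consumer": lk.consumer,
        "a": lk.a, "e": lk.e, "omega": lk.omega,
    }).to_csv(d / "links.csv", index=False)
    state = {
        "B_star": [float(b) for b in community.B_star],
        "original_ids": [int(i) for i in community.original_ids],
        "seed": community.seed,
        "community_id": community.community_id,
    }
    (d / "state.json").write_text(json.dumps(state, indent=1))


def load_community(directory: str | Path) -> Community:
    d = Path(directory)
    for name in ("web.csv", "web.json", "species.csv", "links.csv",
                 "state.json"):
        if not (d / name).exists():
            raise FileNotFoundError(
                f"community bundle at {d} is missing component {name!r}"
            )
    web = load_web(d / "web")
    sp = pd.read_csv(d / "species.csv", float_precision="round_trip")
    lk = pd.read_csv(d / "links.csv", float_precision="round_trip")
    state = json.loads((d / "state.json").read_text())
    return Community(
        web=web,
        species=SpeciesParams(
            M=sp.M.to_numpy(float), r=sp.r.to_numpy(float),
            K=sp.K.to_numpy(float), m=sp.m.to_numpy(float),
            level=sp.level.to_numpy(np.int64),
        ),
        links=LinkParams(
            resource=lk.resource.to_numpy(np.int64),
            consumer=lk.consumer.to_numpy(np.int64),
            a=lk.a.to_numpy(float), e=lk.e.to_numpy(float),
            omega=lk.omega.to_numpy(float),
        ),
        B_star=np.array(state["B_star"], dtype=float),
        original_ids=np.array(state["original_ids"], dtype=np.int64),
        seed=state["seed"],
        community_id=int(state["community_id"]),
    )
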