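"""Message Assessment Framework: the crisis-message catalog and its
deterministic mapping onto theory constructs.

Messages are classified by which persuasive cues they carry — threat (fear
appeals, from the Extended Parallel Process Model), efficacy (self- and
response-efficacy cues, also EPPM), and subjective norm (Theory of Planned
Behavior) — individually or in combination. Each category maps to a fixed
:class:`ConstructProfile` of belief-activation increments; message *text* is
carried for documentation and reporting only and is never interpreted.
"""

from __future__ import annotations

import csv
import enum
import io
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence


class CatalogError(ValueError):
    """Raised for an invalid message catalog (duplicate ids, bad category)."""


class MessageCategory(str, enum.Enum):
    """Framing category of a crisis message."""

    CONTROL = "control"
    FEAR = "fear"
    EFFICACY = "efficacy"
    NORM = "norm"
    FEAR_EFFICACY = "fear_efficacy"
    FEAR_EFFICACY_NORM = "fear_efficacy_norm"


#: Which construct channels each category activates.
_CATEGORY_CHANNELS: dict[MessageCategory, frozenset[str]] = {
    MessageCategory.CONTROL: frozenset(),
    MessageCategory.FEAR: frozenset({"threat"}),
    MessageCategory.EFFICACY: frozenset({"efficacy"}),
    MessageCategory.NORM: frozenset({"norm"}),
    MessageCategory.FEAR_EFFICACY: frozenset({"threat", "efficacy"}),
    MessageCategory.FEAR_EFFICACY_NORM: frozenset({"threat", "efficacy", "norm"}),
}

#: Default belief-activation increments per construct channel. Threat and
#: efficacy cues are weighted above norm cues, reflecting the evidence that
#: they exert the stronger influence on protective action.
DEFAULT_DELTAS: dict[str, float] = {"threat": 0.35, "efficacy": 0.35, "norm": 0.25}


@dataclass(frozen=True)
class ConstructProfile:
    """Belief-activation increments a message applies, each in [0, 1]."""

    delta_threat: float = 0.0
    delta_efficacy: float = 0.0
    delta_norm: float = 0.0

    def __post_init__(self) -> None:
        for name in ("delta_threat", "delta_efficacy", "delta_norm"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise CatalogError(f"{name} must be in [0, 1], got {v!r}")

    @property
    def is_null(self) -> bool:
        return self.delta_threat == self.delta_efficacy == self.delta_norm == 0.0


@dataclass(frozen=True)
class MessageSpec:
    """One catalog entry: id, framing category, text, and activation profile."""

    id: str
    category: MessageCategory
    text: str = ""
    construct_profile: ConstructProfile = field(default_factory=ConstructProfile)

    def __post_init__(self) -> None:
        if self.category is MessageCategory.CONTROL and not self.construct_profile.is_null:
            raise CatalogError(
                f"control message {self.id!r} must carry an all-zero construct profile"
            )


def profile_for(
    category: MessageCategory | str,
    deltas: Mapping[str, float] | None = None,
) -> ConstructProfile:
    """Deterministic category -> construct-profile mapping.

    Channels the category does not name are exactly zero; named channels take
    the configured increment (``DEFAULT_DELTAS`` unless overridden).
    """
    category = MessageCategory(category)
    cfg = dict(DEFAULT_DELTAS)
    if deltas:
        unknown = set(deltas) - set(cfg)
        if unknown:
            raise CatalogError(f"unknown delta channel(s): {sorted(unknown)}")
        cfg.update(deltas)
    channels = _CATEGORY_CHANNELS[category]
    return ConstructProfile(
        delta_threat=cfg["threat"] if "threat" in channels else 0.0,
        delta_efficacy=cfg["efficacy"] if "efficacy" in channels else 0.0,
        delta_norm=cfg["norm"] if "norm" in channels else 0.0,
    )


def _build_message(entry: Mapping[str, object], deltas: Mapping[str, float] | None) -> MessageSpec:
    try:
        category = MessageCategory(str(entry["category"]))
    except ValueError as exc:
        raise CatalogError(f"unknown category {entry.get('category')!r}") from exc
    overrides = entry.get("deltas")
    local = dict(deltas or {})
    if overrides:
        local.update({str(k): float(v) for k, v in dict(overrides).items()})  # type: ignore[call-overload]
    return MessageSpec(
        id=str(entry["id"]),
        category=category,
        text=str(entry.get("text", "")),
        construct_profile=profile_for(category, local or None),
    )


def load_catalog(
    source: str | Path | Iterable[Mapping[str, object]] | None = None,
    *,
    deltas: Mapping[str, float] | None = None,
) -> list[MessageSpec]:
    """Load a message catalog, in document order.

    ``source`` may be a path to a JSON catalog (list of objects with keys
    ``id``, ``category``, ``text`` and optional per-message ``deltas``
    overrides), an already-parsed sequence of such mappings, or ``None`` for
    the packaged default catalog of 16 messages (1 control + 3 variants in
    each of 5 framing categories).
    """
    if source is None:
        raw = resources.files("evactwin.data").joinpath("messages.json").read_text()
        entries = json.loads(raw)
    elif isinstance(source, (str, Path)):
        text = Path(source).read_text()
        entries = json.loads(text)
    else:
        entries = list(source)
    if not isinstance(entries, list):
        raise CatalogError("catalog document must be a list of message objects")

    messages = [_build_message(e, deltas) for e in entries]
    seen: set[str] = set()
    for m in messages:
        if m.id in seen:
            raise CatalogError(f"duplicate message id {m.id!r}")
        seen.add(m.id)
    return messages


def load_catalog_csv(
    source: str | Path | io.TextIOBase,
    *,
    deltas: Mapping[str, float] | None = None,
) -> list[MessageSpec]:
    """Read a catalog from a CSV with columns (variant id, category, content,
    theoretical connection) — the layout of the published message table.

    Category cells are free text; they are normalised by keyword matching
    (e.g. "Combined fear-efficacy" -> fear_efficacy).
    """
    if isinstance(source, (str, Path)):
        handle: io.TextIOBase = open(source, newline="")  # noqa: SIM115
        close = True
    else:
        handle, close = source, False
    try:
        reader = csv.reader(handle)
        rows = [r for r in reader if r and any(c.strip() for c in r)]
    finally:
        if close:
            handle.close()
    if rows and rows[0] and "id" in rows[0][0].lower():
        rows = rows[1:]
    entries = [
        {"id": r[0].strip(), "category": _normalise_category(r[1]), "text": (r[2].strip() if len(r) > 2 else "")}
        for r in rows
    ]
    return load_catalog(entries, deltas=deltas)


def _normalise_category(cell: str) -> str:
    s = cell.strip().lower()
    has_fear = "fear" in s
    has_eff = "efficacy" in s
    has_norm = "norm" in s
    if "control" in s or not (has_fear or has_eff or has_norm):
        return MessageCategory.CONTROL.value
    if has_fear and has_eff and has_norm:
        return MessageCategory.FEAR_EFFICACY_NORM.value
    if has_fear and has_eff:
        return MessageCategory.FEAR_EFFICACY.value
    if has_fear:
        return MessageCategory.FEAR.value
    if has_eff:
        return MessageCategory.EFFICACY.value
    return MessageCategory.NORM.value


def default_grouping(catalog: Sequence[MessageSpec] | None = None) -> dict[str, str]:
    """Map message/condition id -> framing-category label for pooled analyses."""
    if catalog is None:
        catalog = load_catalog()
    return {m.id: m.category.value for m in catalog}
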