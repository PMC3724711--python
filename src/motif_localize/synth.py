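"""Synthetic Swiss-Prot / PROSITE fixture generator with planted truth.

Emulates the two inputs of the pipeline at miniature scale: a protein
database where each compartment has a configurable background frequency and
a controllable fraction of proteins carries a second compartment, and a
motif collection whose TP (and optionally FP) hit sets are drawn with an
odds multiplier ``rho`` towards designated target compartments (``rho = 1``
is the uniform null).  The generator writes the same flat-file dialects the
readers consume and keeps a ground-truth ledger of every planted assignment,
so parsers, counting and the planted-effect recovery of the statistics can
be checked exactly.

The files carry no sequence content (SQ blocks and real consensus patterns
are irrelevant to localization analysis); motifs get dummy descriptors.
Identical configuration (including seed) yields byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .compartments import CompartmentVocabulary

__all__ = [
    "SynthConfigError",
    "MotifSpec",
    "SyntheticConfig",
    "TruthLedger",
    "SyntheticData",
    "generate",
    "null_motif_specs",
    "planted_motif_specs",
    "demo_config",
]

#: Default compartment background frequencies (fraction of the database).
#: Large compartments (cytosol, membrane, nucleus, extracellular) dominate,
#: organelles are rare; the remaining ~30% of proteins stay unlocalized, so
#: coverage denominators are exercised.
DEFAULT_BACKGROUND: Mapping[str, float] = {
    "cyt": 0.22,
    "chl": 0.03,
    "ext": 0.10,
    "Mem": 0.12,
    "Mit": 0.06,
    "Nuc": 0.12,
    "Per": 0.02,
    "Ret": 0.02,
    "Gol": 0.015,
    "Prx": 0.01,
    "Lys": 0.01,
    "Vac": 0.01,
}

#: Non-localization decor keywords and their per-protein rates; includes the
#: bookkeeping keywords excluded by the keyword analysis.
DEFAULT_KEYWORD_DECOR: Mapping[str, float] = {
    "Reference proteome": 0.9,
    "Complete proteome": 0.9,
    "3D-structure": 0.15,
    "Alternative splicing": 0.10,
    "Phosphoprotein": 0.20,
    "Transmembrane": 0.10,
    "Repeat": 0.08,
}


class SynthConfigError(ValueError):
    """The synthetic configuration is invalid or infeasible."""


@dataclass(frozen=True)
class MotifSpec:
    """Plan for one synthetic motif.

    ``tp_rho`` multiplies the sampling odds of proteins localized in any
    ``tp_targets`` compartment when drawing the TP set (``rho = 1``: uniform
    draw, no planted effect).  ``fp_targets=None`` draws the FP set from the
    plain background.
    """

    name: str
    kind: str = "pattern"
    tp_size: int = 20
    fp_size: int = 10
    tp_targets: tuple[str, ...] = ()
    tp_rho: float = 1.0
    fp_targets: tuple[str, ...] | None = None
    fp_rho: float = 1.0


@dataclass(frozen=True)
class SyntheticConfig:
    n_proteins: int = 2000
    background: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BACKGROUND))
    multi_fraction: float = 0.068
    motifs: tuple[MotifSpec, ...] = ()
    keyword_decor: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_KEYWORD_DECOR)
    )
    alias_fraction: float = 0.05
    decoy_flags: int = 2  # extra N-flagged DR entries per motif
    seed: int = 0

    def validate(self, vocab: CompartmentVocabulary) -> None:
        mass = 0.0
        for code, p in self.background.items():
            if code not in vocab:
                raise SynthConfigError(f"background compartment {code!r} not in vocabulary")
            if not 0.0 <= p <= 1.0:
                raise SynthConfigError(f"background[{code}]={p} outside [0, 1]")
            mass += p
        if mass > 1.0 + 1e-9:
            raise SynthConfigError(f"background frequencies sum to {mass} > 1")
        if not 0.0 <= self.multi_fraction <= 1.0:
            raise SynthConfigError("multi_fraction must be in [0, 1]")
        if not 0.0 <= self.alias_fraction <= 1.0:
            raise SynthConfigError("alias_fraction must be in [0, 1]")
        for m in self.motifs:
            if m.kind not in ("pattern", "matrix"):
                raise SynthConfigError(f"{m.name}: kind must be pattern or matrix")
            if m.tp_size + m.fp_size > self.n_proteins:
                raise SynthConfigError(f"{m.name}: tp_size + fp_size > n_proteins")
            if m.tp_rho < 1.0 or m.fp_rho < 1.0:
                raise SynthConfigError(f"{m.name}: rho must be >= 1")
            for targets, rho, side in (
                (m.tp_targets, m.tp_rho, "tp"),
                (m.fp_targets or (), m.fp_rho, "fp"),
            ):
                for code in targets:
                    if rho > 1.0 and self.background.get(code, 0.0) <= 0.0:
                        raise SynthConfigError(
                            f"{m.name}: {side} target {code!r} has zero background "
                            f"mass but rho={rho} demands enrichment"
                        )


@dataclass(frozen=True)
class MotifTruth:
    spec: MotifSpec
    accession: str
    tp_members: frozenset[str]
    fp_members: frozenset[str]


@dataclass(frozen=True)
class TruthLedger:
    """Ground truth of a generated fixture.

    ``proteins`` maps every primary accession to its planted compartment set
    (empty for unlocalized proteins); ``motifs`` records each motif's spec
    and sampled membership.
    """

    proteins: Mapping[str, frozenset[str]]
    motifs: Mapping[str, MotifTruth]

    def localized(self) -> dict[str, frozenset[str]]:
        return {a: c for a, c in self.proteins.items() if c}

    def multi_fraction_observed(self) -> float:
        loc = self.localized()
        if not loc:
            return 0.0
        return sum(1 for c in loc.values() if len(c) >= 2) / len(loc)

    def to_tsv(self) -> str:
        lines = ["#kind\tid\tcompartments\ttp_members\tfp_members"]
        for acc in sorted(self.proteins):
            codes = ",".join(sorted(self.proteins[acc]))
            lines.append(f"protein\t{acc}\t{codes}\t\t")
        for ps in sorted(self.motifs):
            t = self.motifs[ps]
            lines.append(
                "motif\t{}\t{}\t{}\t{}".format(
                    ps,
                    ",".join(sorted(t.spec.tp_targets)),
                    ",".join(sorted(t.tp_members)),
                    ",".join(sorted(t.fp_members)),
                )
            )
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class SyntheticData:
    swissprot_text: str
    prosite_text: str
    truth: TruthLedger


def _wrap_keywords(keywords: Sequence[str], width: int = 70) -> list[str]:
    lines: list[str] = []
    current = ""
    for i, kw in enumerate(keywords):
        token = kw + ("." if i == len(keywords) - 1 else ";")
        if current and len(current) + 1 + len(token) > width:
            lines.append(current)
            current = token
        else:
            current = f"{current} {token}" if current else token
    if current:
        lines.append(current)
    return [f"KW   {line}" for line in lines]


def generate(config: SyntheticConfig) -> SyntheticData:
    """Generate a (Swiss-Prot text, PROSITE text, truth ledger) triple."""
    vocab = CompartmentVocabulary.default("twelve")
    config.validate(vocab)
    rng = np.random.default_rng(config.seed)
    codes = [c for c in vocab.codes if config.background.get(c, 0.0) > 0.0]
    probs = np.array([config.background[c] for c in codes], dtype=float)
    mass = float(probs.sum())
    cond = probs / mass if mass > 0 else probs
    code_to_keyword = {code: kw for kw, code in vocab.keyword_map.items()}
    decor_items = sorted(config.keyword_decor.items())

    proteins: dict[str, frozenset[str]] = {}
    secondary: dict[str, str | None] = {}
    entry_names: dict[str, str] = {}
    sp_lines: list[str] = []
    for i in range(1, config.n_proteins + 1):
        acc = f"P{i:05d}"
        entry = f"S{i:05d}_SYNTH"
        planted: set[str] = set()
        if mass > 0 and rng.random() < mass:
            first = codes[int(rng.choice(len(codes), p=cond))]
            planted.add(first)
            if len(codes) > 1 and rng.random() < config.multi_fraction:
                others = [c for c in codes if c != first]
                w = np.array([config.background[c] for c in others], dtype=float)
                planted.add(others[int(rng.choice(len(others), p=w / w.sum()))])
        alias = f"Q{i:05d}" if rng.random() < config.alias_fraction else None
        keywords = sorted(code_to_keyword[c] for c in planted)
        keywords += [kw for kw, rate in decor_items if rng.random() < rate]
        proteins[acc] = frozenset(planted)
        secondary[acc] = alias
        entry_names[acc] = entry
        sp_lines.append(f"ID   {entry:<24}Reviewed;         100 AA.")
        sp_lines.append(f"AC   {acc};" + (f" {alias};" if alias else ""))
        if keywords:
            sp_lines.extend(_wrap_keywords(sorted(set(keywords))))
        sp_lines.append("//")

    accs = list(proteins)
    motif_truth: dict[str, MotifTruth] = {}
    ps_lines: list[str] = []
    for m_idx, spec in enumerate(config.motifs, start=1):
        ps_acc = f"PS9{m_idx:04d}"
        tp_idx = _weighted_sample(rng, accs, proteins, spec.tp_targets, spec.tp_rho,
                                  spec.tp_size, exclude=frozenset())
        fp_idx = _weighted_sample(rng, accs, proteins, spec.fp_targets or (),
                                  spec.fp_rho, spec.fp_size, exclude=tp_idx)
        taken = tp_idx | fp_idx
        decoys: list[str] = []
        pool = [a for a in accs if a not in taken]
        if config.decoy_flags and pool:
            picks = rng.choice(len(pool), size=min(config.decoy_flags, len(pool)),
                               replace=False)
            decoys = [pool[int(j)] for j in sorted(picks)]
        ps_lines.append(f"ID   {spec.name}; {spec.kind.upper()}.")
        ps_lines.append(f"AC   {ps_acc};")
        ps_lines.append(f"DE   Synthetic motif {spec.name}.")
        if spec.kind == "pattern":
            ps_lines.append("PA   A-C-D-E-x(2)-[FY].")
        else:
            ps_lines.append("MA   /GENERAL_SPEC: ALPHABET='ACDEFY'; LENGTH=6;")
        triplets = []
        for acc in sorted(tp_idx):
            triplets.append((_cited(acc, secondary, rng), entry_names[acc], "T"))
        for acc in sorted(fp_idx):
            triplets.append((_cited(acc, secondary, rng), entry_names[acc], "F"))
        for acc in decoys:
            triplets.append((_cited(acc, secondary, rng), entry_names[acc], "N"))
        for j in range(0, len(triplets), 3):
            chunk = triplets[j : j + 3]
            ps_lines.append(
                "DR   " + " ".join(f"{a}, {e:<12}, {f};" for a, e, f in chunk)
            )
        ps_lines.append("//")
        motif_truth[ps_acc] = MotifTruth(
            spec=spec, accession=ps_acc,
            tp_members=frozenset(tp_idx), fp_members=frozenset(fp_idx),
        )

    return SyntheticData(
        swissprot_text="\n".join(sp_lines) + "\n",
        prosite_text="\n".join(ps_lines) + "\n",
        truth=TruthLedger(proteins=proteins, motifs=motif_truth),
    )


def _cited(acc: str, secondary: Mapping[str, str | None], rng: np.random.Generator) -> str:
    """Cite the secondary accession half the time, when one exists."""
    alias = secondary.get(acc)
    if alias is not None and rng.random() < 0.5:
        return alias
    return acc


def _weighted_sample(
    rng: np.random.Generator,
    accs: Sequence[str],
    proteins: Mapping[str, frozenset[str]],
    targets: Sequence[str],
    rho: float,
    size: int,
    exclude: frozenset[str],
) -> frozenset[str]:
    pool = [a for a in accs if a not in exclude]
    if size > len(pool):
        raise SynthConfigError("set size exceeds available protein pool")
    target_set = frozenset(targets)
    w = np.array(
        [rho if proteins[a] & target_set else 1.0 for a in pool], dtype=float
    )
    picks = rng.choice(len(pool), size=size, replace=False, p=w / w.sum())
    return frozenset(pool[int(j)] for j in picks)


def null_motif_specs(
    n_motifs: int, tp_size: int = 12, fp_size: int = 12
) -> tuple[MotifSpec, ...]:
    """A cohort with no planted effect (rho = 1 everywhere)."""
    return tuple(
        MotifSpec(
            name=f"NULL{i:04d}",
            kind="pattern" if i % 2 else "matrix",
            tp_size=tp_size,
            fp_size=fp_size,
        )
        for i in range(1, n_motifs + 1)
    )


def planted_motif_specs(
    n_motifs: int,
    targets: Sequence[Sequence[str]],
    rho: float = 50.0,
    tp_size: int = 50,
    fp_size: int = 10,
    fp_targets: Sequence[Sequence[str]] | None = None,
    fp_rho: float = 1.0,
) -> tuple[MotifSpec, ...]:
    """A cohort with planted TP (and optionally FP) target compartments.

    ``targets`` (and ``fp_targets``) cycle over the motifs.
    """
    specs = []
    for i in range(n_motifs):
        fp_t = tuple(fp_targets[i % len(fp_targets)]) if fp_targets else None
        specs.append(
            MotifSpec(
                name=f"PLNT{i + 1:04d}",
                kind="pattern" if i % 2 else "matrix",
                tp_size=tp_size,
                fp_size=fp_size,
                tp_targets=tuple(targets[i % len(targets)]),
                tp_rho=rho,
                fp_targets=fp_t,
                fp_rho=fp_rho if fp_t else 1.0,
            )
        )
    return tuple(specs)


def demo_config(seed: int = 0, n_proteins: int = 2000, n_motifs: int = 40) -> SyntheticConfig:
    """A mixed demonstration cohort: planted single/double/triple-target
    motifs of both kinds plus a few null motifs."""
    rng = np.random.default_rng(seed)
    codes = [c for c, p in DEFAULT_BACKGROUND.items() if p > 0]
    specs: list[MotifSpec] = []
    for i in range(1, n_motifs + 1):
        if i % 8 == 0:
            specs.append(MotifSpec(name=f"SYN{i:04d}", kind="matrix" if i % 2 else "pattern",
                                   tp_size=15, fp_size=8))
            continue
        k = int(rng.choice([1, 1, 1, 2, 2, 3]))
        targets = tuple(rng.choice(codes, size=k, replace=False))
        fp_t = tuple(rng.choice(codes, size=1)) if rng.random() < 0.3 else None
        specs.append(
            MotifSpec(
                name=f"SYN{i:04d}",
                kind="matrix" if i % 2 else "pattern",
                tp_size=int(rng.integers(20, 60)),
                fp_size=int(rng.integers(5, 20)),
                tp_targets=targets,
                tp_rho=float(rng.choice([10.0, 25.0, 50.0])),
                fp_targets=fp_t,
                fp_rho=25.0 if fp_t else 1.0,
            )
        )
    return SyntheticConfig(n_proteins=n_proteins, motifs=tuple(specs), seed=seed)
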