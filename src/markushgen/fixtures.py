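"""Synthetic analog series with known ground truth, plus packaged tables.

``generate_series`` assembles an analog series by bonding one chosen
substituent per attachment position onto a fixed core, sampling
combinations without replacement under a seed, so every other module can
be exercised against a known (core, per-position substituent sets) answer.

``packaged_tables`` returns the two reference top-10 R-group occurrence
tables shipped with the package (one from a patent-derived fragment
library, one from approved drugs), transcribed with their printed SMILES
and percentages. The "Trifulromethyl" misspelling in the drugs table is
preserved in ``printed_name`` and normalized in ``name``.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from importlib import resources
from io import StringIO

import pandas as pd
from rdkit import Chem

from .chemio import canonical_key, write_sdf
from .errors import InvalidArgument, ParseError
from .libbuilder import LibraryEntry, RGroupLibrary
from .taxonomy import Taxonomy, categorize, fragment_key


@dataclass
class SeriesSpec:
    """Recipe for one synthetic analog series.

    ``core_smiles`` carries numbered attachment dummies ``[*:1]``..``[*:k]``;
    ``position_choices`` maps "R1".."Rk" to candidate fragment SMILES (each
    with exactly one attachment atom). ``n`` compounds are sampled without
    replacement from the full combination space.
    """

    core_smiles: str
    position_choices: dict[str, list[str]]
    n: int
    seed: int = 0
    name: str = "series"


@dataclass
class GroundTruth:
    core_smiles: str  # bare core, attachment dummies removed
    positions: dict[str, set[str]] = field(default_factory=dict)  # label -> keys used


def _core_with_maps(spec: SeriesSpec) -> Chem.Mol:
    core = Chem.MolFromSmiles(spec.core_smiles)
    if core is None:
        raise ParseError(f"unparseable core SMILES: {spec.core_smiles!r}")
    maps = sorted(
        a.GetAtomMapNum() for a in core.GetAtoms() if a.GetAtomicNum() == 0
    )
    expected = list(range(1, len(spec.position_choices) + 1))
    if maps != expected:
        raise InvalidArgument(
            f"core attachment maps {maps} do not match positions {expected}"
        )
    return core


def _bare_core_smiles(core: Chem.Mol) -> str:
    rw = Chem.RWMol(core)
    for idx in sorted(
        (a.GetIdx() for a in rw.GetAtoms() if a.GetAtomicNum() == 0), reverse=True
    ):
        rw.RemoveAtom(idx)
    bare = rw.GetMol()
    Chem.SanitizeMol(bare)
    return canonical_key(bare).key


def _fragment_mol(smiles: str, map_num: int) -> Chem.Mol:
    smi = "*[H]" if smiles in ("*H", "H*") else smiles
    mol = Chem.MolFromSmiles(smi)
    if mol is None:
        raise ParseError(f"unparseable fragment SMILES: {smiles!r}")
    dummies = [a for a in mol.GetAtoms() if a.GetAtomicNum() == 0]
    if len(dummies) != 1:
        raise InvalidArgument(f"fragment {smiles!r} must have exactly one '*'")
    dummies[0].SetAtomMapNum(map_num)
    return mol


def assemble(core: Chem.Mol, fragments: dict[str, str]) -> Chem.Mol:
    """Bond one fragment SMILES per position label onto a mapped core."""
    combo = Chem.Mol(core)
    for label, smiles in fragments.items():
        map_num = int(label[1:])
        combo = Chem.CombineMols(combo, _fragment_mol(smiles, map_num))
    zipped = Chem.molzip(combo)
    zipped = Chem.RemoveHs(zipped)
    Chem.SanitizeMol(zipped)
    return zipped


def generate_series(
    spec: SeriesSpec, sdf_path: str | None = None
) -> tuple[list[Chem.Mol], GroundTruth]:
    """Sample ``spec.n`` distinct compounds; reproducible under the seed.

    Returns the molecules (file order = sample order) and the ground truth:
    the bare core plus the per-position substituent key sets actually used.
    """
    core = _core_with_maps(spec)
    labels = sorted(spec.position_choices, key=lambda s: int(s[1:]))
    sizes = [len(spec.position_choices[lab]) for lab in labels]
    total = 1
    for s in sizes:
        total *= s
    if spec.n > total or spec.n < 1:
        raise InvalidArgument(f"cannot sample {spec.n} of {total} combinations")
    rng = random.Random(spec.seed)
    picks = sorted(rng.sample(range(total), spec.n))
    truth = GroundTruth(core_smiles=_bare_core_smiles(core))
    mols: list[Chem.Mol] = []
    for serial, index in enumerate(picks, start=1):
        combo: dict[str, str] = {}
        rest = index
        for lab, size in zip(labels, sizes):
            rest, digit = divmod(rest, size)
            combo[lab] = spec.position_choices[lab][digit]
        mol = assemble(core, combo)
        mol.SetProp("_Name", f"{spec.name}-{serial}")
        mols.append(mol)
        for lab, smi in combo.items():
            truth.positions.setdefault(lab, set()).add(fragment_key(smi))
    if sdf_path is not None:
        write_sdf(mols, sdf_path)
    return mols, truth


# ---------------------------------------------------------------------------
# validation battery for round-trip recovery

# Substituent pool with pairwise-distinct first atoms, so that any two
# distinct choices at a position diverge immediately and the intended core
# stays the true MCS of the sampled series.
DIVERGENT_FRAGMENTS = ["*C", "*F", "*Cl", "*Br", "*I", "*O", "*N", "*S", "*[H]"]

# Core templates, 6-20 heavy atoms, 1-4 attachment positions.
CORE_TEMPLATES = [
    "c1ccc([*:1])cc1",
    "C1CCC([*:1])CC1",
    "c1ccnc([*:1])c1",
    "c1cc([*:1])ccc1[*:2]",
    "C1CC([*:1])CC([*:2])C1",
    "O=C(Nc1ccc([*:1])cc1)C[*:2]",
    "c1cc([*:1])cc([*:2])c1C([*:3])C#N",
    "c1cc([*:2])c2cc([*:1])ccc2c1",
    "C(c1ccc([*:1])cc1)c1ccc([*:2])cc1",
    "c1c([*:1])cc([*:2])c(CC([*:3])C[*:4])c1",
]


def validation_specs(count: int, seed: int) -> list[SeriesSpec]:
    """Seeded battery of series specs whose intended core is the series MCS.

    Each position draws 2-6 candidates from a pool of substituents with
    pairwise-distinct first atoms, and sampling is repeated until every
    position actually varies within the sampled members (a constant
    position would fold its substituent into the core).
    """
    rng = random.Random(seed)
    specs: list[SeriesSpec] = []
    attempt = 0
    while len(specs) < count:
        attempt += 1
        template = rng.choice(CORE_TEMPLATES)
        n_pos = template.count("[*:")
        choices = {
            f"R{i}": rng.sample(DIVERGENT_FRAGMENTS, rng.randint(2, 6))
            for i in range(1, n_pos + 1)
        }
        total = 1
        for c in choices.values():
            total *= len(c)
        n = min(total, rng.randint(max(3, n_pos + 1), 8))
        spec = SeriesSpec(
            core_smiles=template,
            position_choices=choices,
            n=n,
            seed=rng.randrange(2**31),
            name=f"val{len(specs)}",
        )
        _, truth = generate_series(spec)
        if all(len(used) >= 2 for used in truth.positions.values()):
            specs.append(spec)
        if attempt > 50 * count:  # pragma: no cover - safety valve
            raise RuntimeError("validation spec sampling did not converge")
    return specs


# ---------------------------------------------------------------------------
# packaged reference tables


def _raw_tables() -> pd.DataFrame:
    text = resources.files("markushgen.data").joinpath("top_r_groups.csv").read_text()
    return pd.read_csv(StringIO(text))


def packaged_tables() -> tuple[pd.DataFrame, pd.DataFrame]:
    """The two shipped top-10 occurrence tables (library, approved drugs).

    Columns: name, printed_name, smiles (as printed), key (canonical),
    percent. Rows keep their printed order.
    """
    raw = _raw_tables()
    out = []
    for which in ("library", "drugs"):
        table = raw[raw["table"] == which].copy()
        table["key"] = [fragment_key(s) for s in table["smiles"]]
        table = table[["name", "printed_name", "smiles", "key", "percent"]]
        out.append(table.reset_index(drop=True))
    return out[0], out[1]


def packaged_library(tax: Taxonomy | None = None) -> RGroupLibrary:
    """The shipped reference library: the top-10 table as percent-ranked
    entries (no raw counts survive transcription, so ``count`` is a rank
    placeholder of 0 and ``percent`` carries the printed value)."""
    tax = tax or Taxonomy.default()
    table, _ = packaged_tables()
    entries = [
        LibraryEntry(
            smiles=row.key,
            count=0,
            categories={categorize(row.key, tax)},
            percent=row.percent,
        )
        for row in table.itertuples()
    ]
    return RGroupLibrary(
        entries=entries,
        meta={"source": "transcribed reference top-10 occurrence table"},
    )
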