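"""Claim-document rendering: Word (.docx), Markdown, and a structure scheme.

The .docx writer emits a minimal OOXML package directly (a zip holding
``[Content_Types].xml``, the package relationships, and
``word/document.xml``), with the scheme embedded as a PNG when the
structure renderer supports raster output. Clause *text* is the only
contract — the docx and Markdown renderings carry identical clause strings
and tests assert on those, never on image pixels.

The scheme itself is a 2D depiction of the core with "R1".."Rn" shown at
the attachment positions; the SVG additionally carries the labels as real
``<text>`` elements so they are machine-checkable.
"""

from __future__ import annotations

import zipfile
from dataclasses import dataclass, field
from xml.etree import ElementTree
from xml.sax.saxutils import escape

from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Chem.Draw import rdMolDraw2D

from .errors import ValidationError
from .scaffolding import ScaffoldCore


@dataclass
class ClaimDocument:
    title: str
    clauses: list[tuple[int, str]] = field(default_factory=list)
    scheme: ScaffoldCore | None = None
    notes: list[str] = field(default_factory=list)

    def validate(self) -> None:
        if not self.clauses:
            raise ValidationError("claim document has no clauses")
        numbers = [n for n, _ in self.clauses]
        if numbers != list(range(1, len(numbers) + 1)):
            raise ValidationError(f"clause numbers not consecutive from 1: {numbers}")


def _annotated_core(core: ScaffoldCore) -> Chem.Mol:
    """Copy of the core with a labeled dummy atom per attachment position."""
    rw = Chem.RWMol(core.core)
    for pos in core.positions:
        dummy = Chem.Atom(0)
        didx = rw.AddAtom(dummy)
        rw.AddBond(pos.core_atom, didx, Chem.BondType.SINGLE)
        rw.GetAtomWithIdx(didx).SetProp("atomLabel", pos.label)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    AllChem.Compute2DCoords(mol)
    return mol


def depict_core(core: ScaffoldCore, width: int = 400, height: int = 300) -> str:
    """SVG depiction of the core with R labels at attachment positions."""
    mol = _annotated_core(core)
    drawer = rdMolDraw2D.MolDraw2DSVG(width, height)
    drawer.DrawMolecule(mol)
    # overlay searchable/visible text labels at the dummy-atom positions
    label_xy = []
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 0 and atom.HasProp("atomLabel"):
            point = drawer.GetDrawCoords(atom.GetIdx())
            label_xy.append((atom.GetProp("atomLabel"), point.x, point.y))
    drawer.FinishDrawing()
    svg = drawer.GetDrawingText()
    overlays = "".join(
        f"<text x='{x:.1f}' y='{y - 8:.1f}' font-size='13' "
        f"text-anchor='middle' fill='#1133AA'>{escape(label)}</text>\n"
        for label, x, y in label_xy
    )
    return svg.replace("</svg>", overlays + "</svg>")


def _scheme_png(core: ScaffoldCore, width: int = 400, height: int = 300) -> bytes | None:
    try:
        drawer = rdMolDraw2D.MolDraw2DCairo(width, height)
    except Exception:  # renderer built without raster support
        return None
    drawer.DrawMolecule(_annotated_core(core))
    drawer.FinishDrawing()
    return drawer.GetDrawingText()


# --- minimal OOXML plumbing -------------------------------------------------

_CONTENT_TYPES = """<?xml version="1.0" encoding="UTF-8" standalone="yes"?>
<Types xmlns="http://schemas.openxmlformats.org/package/2006/content-types">
<Default Extension="rels" ContentType="application/vnd.openxmlformats-package.relationships+xml"/>
<Default Extension="xml" ContentType="application/xml"/>
<Default Extension="png" ContentType="image/png"/>
<Override PartName="/word/document.xml" ContentType="application/vnd.openxmlformats-officedocument.wordprocessingml.document.main+xml"/>
</Types>
"""

_ROOT_RELS = """<?xml version="1.0" encoding="UTF-8" standalone="yes"?>
<Relationships xmlns="http://schemas.openxmlformats.org/package/2006/relationships">
<Relationship Id="rId1" Type="http://schemas.openxmlformats.org/officeDocument/2006/relationships/officeDocument" Target="word/document.xml"/>
</Relationships>
"""

_DOC_RELS_IMAGE = """<?xml version="1.0" encoding="UTF-8" standalone="yes"?>
<Relationships xmlns="http://schemas.openxmlformats.org/package/2006/relationships">
<Relationship Id="rIdImg1" Type="http://schemas.openxmlformats.org/officeDocument/2006/relationships/image" Target="media/scheme.png"/>
</Relationships>
"""

_DOC_RELS_EMPTY = """<?xml version="1.0" encoding="UTF-8" standalone="yes"?>
<Relationships xmlns="http://schemas.openxmlformats.org/package/2006/relationships"/>
"""

_W = "http://schemas.openxmlformats.org/wordprocessingml/2006/main"


def _paragraph(text: str, bold: bool = False) -> str:
    runs = []
    pieces = text.split("\n")
    for i, piece in enumerate(pieces):
        if i:
            runs.append("<w:r><w:br/></w:r>")
        props = "<w:rPr><w:b/></w:rPr>" if bold else ""
        runs.append(f'<w:r>{props}<w:t xml:space="preserve">{escape(piece)}</w:t></w:r>')
    return f"<w:p>{''.join(runs)}</w:p>"


def _image_paragraph(cx: int, cy: int) -> str:
    return (
        "<w:p><w:r><w:drawing>"
        f'<wp:inline xmlns:wp="http://schemas.openxmlformats.org/drawingml/2006/wordprocessingDrawing">'
        f'<wp:extent cx="{cx}" cy="{cy}"/>'
        '<wp:docPr id="1" name="scheme"/>'
        '<a:graphic xmlns:a="http://schemas.openxmlformats.org/drawingml/2006/main">'
        '<a:graphicData uri="http://schemas.openxmlformats.org/drawingml/2006/picture">'
        '<pic:pic xmlns:pic="http://schemas.openxmlformats.org/drawingml/2006/picture">'
        '<pic:nvPicPr><pic:cNvPr id="1" name="scheme.png"/><pic:cNvPicPr/></pic:nvPicPr>'
        '<pic:blipFill><a:blip xmlns:r="http://schemas.openxmlformats.org/officeDocument/2006/relationships" r:embed="rIdImg1"/><a:stretch><a:fillRect/></a:stretch></pic:blipFill>'
        f'<pic:spPr><a:xfrm><a:off x="0" y="0"/><a:ext cx="{cx}" cy="{cy}"/></a:xfrm>'
        '<a:prstGeom prst="rect"><a:avLst/></a:prstGeom></pic:spPr>'
        "</pic:pic></a:graphicData></a:graphic></wp:inline>"
        "</w:drawing></w:r></w:p>"
    )


def write_docx(doc: ClaimDocument, path: str) -> None:
    """Write the claim document as a well-formed .docx.

    The scheme PNG (when renderable) is placed after the first sentence of
    clause 1, mirroring the convention of showing the Markush scheme before
    the R-group definitions.
    """
    doc.validate()
    png = _scheme_png(doc.scheme) if doc.scheme is not None else None
    body: list[str] = [_paragraph(doc.title, bold=True)]
    for number, text in doc.clauses:
        first, *rest = text.split("\n")
        body.append(_paragraph(f"{number}. {first}"))
        if number == 1 and png is not None:
            # 400x300 px at 96 dpi in EMU (1 px = 9525 EMU)
            body.append(_image_paragraph(400 * 9525, 300 * 9525))
        if rest:
            body.append(_paragraph("\n".join(rest)))
    if doc.notes:
        body.append(_paragraph("Notes (machine-added breadth):", bold=True))
        for note in doc.notes:
            body.append(_paragraph(note))
    document = (
        '<?xml version="1.0" encoding="UTF-8" standalone="yes"?>'
        f'<w:document xmlns:w="{_W}"><w:body>{"".join(body)}</w:body></w:document>'
    )
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("[Content_Types].xml", _CONTENT_TYPES)
        zf.writestr("_rels/.rels", _ROOT_RELS)
        zf.writestr(
            "word/_rels/document.xml.rels",
            _DOC_RELS_IMAGE if png is not None else _DOC_RELS_EMPTY,
        )
        zf.writestr("word/document.xml", document)
        if png is not None:
            zf.writestr("word/media/scheme.png", png)


def read_docx_text(path: str) -> list[str]:
    """Paragraph texts of a .docx (line breaks restored); used for round-trips."""
    with zipfile.ZipFile(path) as zf:
        root = ElementTree.fromstring(zf.read("word/document.xml"))
    paragraphs = []
    for para in root.iter(f"{{{_W}}}p"):
        parts = []
        for node in para.iter():
            if node.tag == f"{{{_W}}}t":
                parts.append(node.text or "")
            elif node.tag == f"{{{_W}}}br":
                parts.append("\n")
        if parts:
            paragraphs.append("".join(parts))
    return paragraphs


def write_markdown(doc: ClaimDocument, path: str, svg_path: str | None = None) -> None:
    """Markdown rendering with the same clause text as the docx."""
    doc.validate()
    lines = [f"# {doc.title}", ""]
    if doc.scheme is not None and svg_path is not None:
        with open(svg_path, "w") as fh:
            fh.write(depict_core(doc.scheme))
        lines += [f"![Formula (I)]({svg_path})", ""]
    for number, text in doc.clauses:
        first, *rest = text.split("\n")
        lines.append(f"{number}. {first}")
        lines += [f"   {line}" for line in rest]
        lines.append("")
    if doc.notes:
        lines.append("## Notes (machine-added breadth)")
        lines += [f"- {note}" for note in doc.notes]
        lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))
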