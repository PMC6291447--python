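"""Ingest folding free-energy changes and apply the 2 kcal/mol rule."""

import tempfile
from pathlib import Path

from sasdiag import high_ddg, parse_foldx_output

dif_text = "GA12V;\t3.25\nAA33T;\t0.50\nLA7P;\t2.75\nKA40E;\t2.00\n"

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "dif.fxout"
    path.write_text(dif_text)
    records = parse_foldx_output(path, structure_id="demo")

print("variant  ddG (kcal/mol)  high destabilisation?")
for rec in records:
    wt, pos, mut = rec.variant_key
    print(f"{wt}{pos}{mut:5}   {rec.ddg:5.2f}           {high_ddg(rec.ddg)}")
print()
print("ddG is mutant minus wild-type folding free energy. Strictly more")
print("than 2 kcal/mol flags high destabilisation, so 2.00 does not")
print("qualify while 2.75 and 3.25 do; the flag selects the firm")
print("'Disrupt ...' tier of the diagnosis tree.")
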