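# Bundled substitution models

Published empirical amino-acid substitution models, stored in the PAML
`.dat` layout (19 lower-triangular rows of exchangeabilities, then the 20
equilibrium frequencies, residues in the order A R N D C Q E G H I L K M
F P S T W Y V). Exchangeability scales are the original publications'
arbitrary conventions; only relative values matter.

| file | model | source |
|------|-------|--------|
| `LG.dat` | LG | Le & Gascuel (2008), *Mol Biol Evol* 25:1307–1320 |
| `WAG.dat` | WAG | Whelan & Goldman (2001), *Mol Biol Evol* 18:691–699 |
| `mtREV24.dat` | mtREV24 | Adachi & Hasegawa (1996), *J Mol Evol* 42:459–468 |
| `mtArt.dat` | mtArt | Abascal, Posada & Zardoya (2007), *Mol Biol Evol* 24:1–5 |
| `mtZoa.dat` | mtZoa | Rota-Stabelli, Yang & Telford (2009), *Mol Phylogenet Evol* 52:268–272 |

Values were transcribed from the copies of these published matrices
distributed with the R package phangorn (v2.12), with frequencies
renormalized to sum to exactly 1 and rewritten by this package's own
PAML writer at 12 significant digits.

The mtMet, mtVer and mtInv mitochondrial models are not bundled: no
redistributable copy was available when this package was assembled. Any
model in this layout can be dropped into an analysis with
`mtsubst.models.read_model`.
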