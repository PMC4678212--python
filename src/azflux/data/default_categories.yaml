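# Default functional-category keyword rules for abscission transcriptomes.
# Matching is case-insensitive substring against the free-text gene
# description.  A rule with reassign_to moves its matches out of the named
# source category into the target (GH9A1/KORRIGAN-like cellulases belong
# with cellulose biosynthesis, not wall disassembly).  This is an editable
# reconstruction from exemplar gene names; adjust to your annotation style.
categories:
  - name: cellulases
    include: ["cellulase", "glycoside hydrolase family 9", "glycoside hydrolase 9", "endo-1,4-beta-glucanase"]
  - name: cellulose_biosynthesis
    include: ["cellulose synthase", "cesa"]
  - name: cellulases
    include: ["9a1", "korrigan"]
    reassign_to: cellulose_biosynthesis
  - name: polygalacturonases
    include: ["polygalacturonase", "pectin lyase", "pectate lyase"]
  - name: expansins
    include: ["expansin"]
  - name: expansins_alpha
    include: ["alpha-expansin", "expansin a"]
  - name: expansins_beta
    include: ["beta-expansin", "expansin b"]
  - name: xths
    include: ["xyloglucan endotransglucosylase", "xyloglucan endotransglycosylase", "xth"]
  - name: pr_genes
    include: ["pathogenesis-related", "thaumatin", "chitinase", "beta-1,3-glucanase", "kunitz"]
  - name: par1
    include: ["par1", "photoassimilate-responsive"]
  - name: wax_suberin
    include: ["wax", "suberin", "gdsl", "lipid-transfer protein", "lipid transfer protein", "cer4", "fatty acyl-coa reductase"]
  - name: peroxidase_laccase
    include: ["peroxidase", "laccase"]
    exclude: ["ascorbate peroxidase"]
  - name: callose_synthase
    include: ["callose synthase"]
  - name: wall_proteins
    include: ["extensin", "arabinogalactan", "hydroxyproline-rich glycoprotein", "glycine-rich cell wall", "proline-rich cell wall"]
  - name: ethylene
    include: ["1-aminocyclopropane-1-carboxylate", "acc synthase", "acc oxidase"]
  - name: auxin
    include: ["auxin efflux carrier", "pin3", "indole-3-acetic acid-amido", "saur", "aux/iaa"]
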