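# Patterns marking a function string as vague (generic, uninformative).
# One regular expression per line, matched case-insensitively against the
# whole function string with re.fullmatch unless the line starts with "~",
# in which case re.search is used. Lines starting with "#" are comments.
# Users may extend this list via annotation_status.load_vague_patterns().
~\bhypothetical\b
~\buncharacteri[sz]ed\b
~\bunknown function\b
~\bDUF\d+
putative(\s+protein)?
predicted protein
expressed protein
conserved protein
conserved domain protein
membrane protein
ATPase
GTPase
kinase
hydrolase
oxidoreductase
methyltransferase
transferase
dehydrogenase
transporter
permease
transcriptional regulator
DNA-binding protein
RNA-binding protein
metal-binding protein
lipoprotein
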