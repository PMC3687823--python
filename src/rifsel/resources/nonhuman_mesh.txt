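# MeSH descriptors denoting non-human organisms, used by the citation
# filter: a citation is dropped when any of these headings is present
# and "Humans" is absent.  One descriptor per line; '#' starts a comment.
Animals
Mice
Mice, Inbred C57BL
Mice, Knockout
Mice, Transgenic
Rats
Rats, Sprague-Dawley
Rats, Wistar
Saccharomyces cerevisiae
Drosophila
Drosophila melanogaster
Caenorhabditis elegans
Zebrafish
Cattle
Dogs
Rabbits
Swine
Chickens
Sheep
Horses
Xenopus laevis
Escherichia coli
Arabidopsis
Plants
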