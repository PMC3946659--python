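>NLS1 a58 minor-site selective NLS
GSWAGRKRTWRDAF
>NLS2 b6 minor-site selective NLS
GSSSHRKRKFSDAF
>NLS3 b141 minor-site selective NLS
GSRVQRKRKWSEAF
>NLS4 a28 minor-site selective NLS
GSIGRKRGYSVAFG
>NLS5 GuNLS C-terminal NLS of mouse RNA helicase II/Gu
GSRGQKRSFSKAFGQ
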