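region_id	name
aberdeenshire	Aberdeenshire
cambridgeshire	Cambridgeshire
cornwall	Cornwall
cumbria	Cumbria
derbyshire	Derbyshire
devon	Devon
dorset	Dorset
dumfries_and_galloway	Dumfries and Galloway
durham	Durham
east_ayrshire	East Ayrshire
essex	Essex
fife	Fife
glamorgan	Glamorgan
greater_london	Greater London
greater_manchester	Greater Manchester
gwynedd	Gwynedd
hampshire	Hampshire
kent	Kent
lancashire	Lancashire
leicestershire	Leicestershire
lincolnshire	Lincolnshire
merseyside	Merseyside
norfolk	Norfolk
north_yorkshire	North Yorkshire
northamptonshire	Northamptonshire
northumberland	Northumberland
nottinghamshire	Nottinghamshire
oxfordshire	Oxfordshire
somerset	Somerset
stirling	Stirling
suffolk	Suffolk
surrey	Surrey
tyne_and_wear	Tyne and Wear
west_lothian	West Lothian
west_midlands	West Midlands
west_yorkshire	West Yorkshire
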