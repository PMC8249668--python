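bob	person
john	person
mary	person
alice	person
david	person
sarah	person
michael	person
silva	person
anderson	person
toews	person
cobb	person
muslera	person
messi	person
ronaldo	person
crosby	person
mcdavid	person
toronto	location
boston	location
chicago	location
london	location
paris	location
moscow	location
russia	location
canada	location
england	location
nigeria	location
uruguay	location
france	location
nhl	organization
nfl	organization
mlb	organization
nba	organization
fifa	organization
uefa	organization
ufc	organization
bellator	organization
espn	organization
tsn	organization
steelers	organization
lions	organization
bruins	organization
leafs	organization
dollars	money
cents	money
bucks	money
euros	money
pounds	money
percent	percent
percentage	percent
pct	percent
monday	date
tuesday	date
wednesday	date
thursday	date
friday	date
saturday	date
sunday	date
january	date
february	date
march	date
april	date
june	date
july	date
august	date
september	date
october	date
november	date
december	date
noon	time
midnight	time
overtime	time
halftime	time
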